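"""Bundled synthetic gene-set fixtures.

The shipped GMT files are *synthetic* stand-ins for the published
collections the analysis normally consumes (28 tumor-microenvironment
cell-type signatures, hallmark-style pathway sets, 18 treatment-biology
process signatures, and ESTIMATE-style stromal/immune signatures).
Their gene memberships are drawn from the synthetic cohort generator's
gene universe, aligned with its planted co-expression blocks, so that
enrichment analyses on generated cohorts behave like the real
collections on real data.  Replace them with user GMTs (e.g. MSigDB
downloads) for real cohorts.
"""

from __future__ import annotations

from importlib import resources as _res

import numpy as np

from . import synthetic as _syn
from .io import read_gene_sets

__all__ = [
    "load_bundled",
    "bundled_names",
    "synthetic_tme_sets",
    "synthetic_estimate_sets",
    "synthetic_hallmark_sets",
    "synthetic_process_sets",
]

_BUNDLED = {
    "tme28": "synthetic_tme28.gmt",
    "estimate": "synthetic_estimate.gmt",
    "hallmark": "synthetic_hallmark.gmt",
    "processes18": "synthetic_processes18.gmt",
}

PROCESS_SIGNATURES = (
    "CD8_T_effector", "DNA_damage_repair", "Antigen_processing_machinery",
    "Immune_checkpoint", "Cell_cycle_regulators", "Fanconi_anemia",
    "Pan_F_TBRS", "EMT1", "EMT2", "EMT3", "WNT_targets", "FGFR3_related",
    "Cell_cycle", "Mismatch_repair", "Homologous_recombination",
    "Nucleotide_excision_repair", "DNA_replication", "Base_excision_repair",
)

# immune-flavored processes draw from the adaptive TME block, the
# stromal/EMT-flavored ones from innate + stromal rows; the DNA repair
# and cell-cycle sets come from the null region so they carry no pattern
# signal by construction.
_IMMUNE_PROCESSES = frozenset(
    {"CD8_T_effector", "Antigen_processing_machinery", "Immune_checkpoint"}
)
_STROMAL_PROCESSES = frozenset({"Pan_F_TBRS", "EMT1", "EMT2", "EMT3"})

_NULL_REGION = (400, 1500)  # gene rows free of planted shifts at defaults


def synthetic_tme_sets() -> dict[str, set[str]]:
    """The 28 cell-type signatures: each cell type's 10 planted genes."""
    return {
        ct: {_syn.gene_name(r) for r in _syn.tme_set_rows(ct)}
        for ct in _syn.TME_CELL_TYPES
    }


def synthetic_estimate_sets() -> dict[str, set[str]]:
    stromal = {
        _syn.gene_name(r)
        for r in range(_syn.STROMAL_BLOCK_START,
                       _syn.STROMAL_BLOCK_START + _syn.TME_GENES_PER_SET)
    }
    immune = {
        _syn.gene_name(r)
        for r in range(_syn.IMMUNE_BLOCK_START,
                       _syn.IMMUNE_BLOCK_START + _syn.TME_GENES_PER_SET)
    }
    return {"STROMAL_SIGNATURE": stromal, "IMMUNE_SIGNATURE": immune}


def _draw(rng: np.random.Generator, rows: list[int], size: int) -> set[str]:
    pick = rng.choice(len(rows), size=size, replace=False)
    return {_syn.gene_name(rows[i]) for i in pick}


def synthetic_hallmark_sets(n_null: int = 14, set_size: int = 15,
                            seed: int = 20240501) -> dict[str, set[str]]:
    """Hallmark-style pathway collection: 3 immune-linked, 3 stromal-linked
    and ``n_null`` signal-free sets of ``set_size`` genes each."""
    rng = np.random.default_rng(seed)
    adaptive_rows = [
        r for ct in _syn.ADAPTIVE_CELL_TYPES for r in _syn.tme_set_rows(ct)
    ]
    innate_rows = [
        r for ct in _syn.INNATE_CELL_TYPES for r in _syn.tme_set_rows(ct)
    ]
    null_rows = list(range(*_NULL_REGION))
    sets: dict[str, set[str]] = {}
    for i in range(3):
        sets[f"HALLMARK_IMMUNE_{i+1}"] = _draw(rng, adaptive_rows, set_size)
    for i in range(3):
        sets[f"HALLMARK_STROMAL_{i+1}"] = _draw(rng, innate_rows, set_size)
    for i in range(n_null):
        sets[f"HALLMARK_NULL_{i+1:02d}"] = _draw(rng, null_rows, set_size)
    return sets


def synthetic_process_sets(set_size: int = 12, seed: int = 20240502
                           ) -> dict[str, set[str]]:
    """The 18 treatment-biology process signatures (synthetic memberships)."""
    rng = np.random.default_rng(seed)
    adaptive_rows = [
        r for ct in _syn.ADAPTIVE_CELL_TYPES for r in _syn.tme_set_rows(ct)
    ]
    stromal_rows = [
        r for ct in _syn.INNATE_CELL_TYPES for r in _syn.tme_set_rows(ct)
    ] + list(range(_syn.STROMAL_BLOCK_START,
                   _syn.STROMAL_BLOCK_START + _syn.TME_GENES_PER_SET))
    null_rows = list(range(*_NULL_REGION))
    sets: dict[str, set[str]] = {}
    for name in PROCESS_SIGNATURES:
        if name in _IMMUNE_PROCESSES:
            rows = adaptive_rows
        elif name in _STROMAL_PROCESSES:
            rows = stromal_rows
        else:
            rows = null_rows
        sets[name] = _draw(rng, rows, set_size)
    return sets


def bundled_names() -> list[str]:
    return sorted(_BUNDLED)


def load_bundled(name: str) -> dict[str, set[str]]:
    """Load one of the bundled synthetic GMT fixtures by short name
    (``tme28``, ``estimate``, ``hallmark``, ``processes18``)."""
    if name not in _BUNDLED:
        raise KeyError(f"unknown bundled collection {name!r}; "
                       f"choose from {bundled_names()}")
    ref = _res.files("methpattern.resources") / _BUNDLED[name]
    with _res.as_file(ref) as path:
        return read_gene_sets(path)
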