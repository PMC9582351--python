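"""The 24 DNA methylation regulator genes.

DNA methylation at CpG dinucleotides is maintained by three functional
classes of proteins: *writers* (the DNA methyltransferases, which deposit
5-methylcytosine), *erasers* (the TET dioxygenases, which initiate active
demethylation), and *readers* (methyl-CpG binding proteins and
glycosylases that interpret or process the mark).  The 24 genes below form
the feature space on which modification patterns are discovered.
"""

from __future__ import annotations

import pandas as pd

WRITERS = ("DNMT1", "DNMT3A", "DNMT3B")
ERASERS = ("TET1", "TET2", "TET3")
READERS = (
    "MBD1", "MBD2", "MBD3", "MBD4",
    "ZBTB33", "ZBTB38", "ZBTB4", "ZBTB24",
    "UHRF1", "UHRF2", "MECP2", "UNG",
    "TDG", "NTHL1", "SMUG1", "NSUN2", "MGMT", "DMAP1",
)

#: symbol -> functional category, in canonical order (writers, erasers, readers)
REGULATORS: dict[str, str] = {
    **{g: "writer" for g in WRITERS},
    **{g: "eraser" for g in ERASERS},
    **{g: "reader" for g in READERS},
}

REGULATOR_SYMBOLS: tuple[str, ...] = tuple(REGULATORS)


def regulator_table() -> pd.DataFrame:
    """Return the regulator catalogue as a two-column DataFrame.

    Columns are ``symbol`` and ``category`` (writer/eraser/reader); row
    order is the canonical enumeration order.
    """
    return pd.DataFrame(
        {"symbol": list(REGULATORS), "category": list(REGULATORS.values())}
    )
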