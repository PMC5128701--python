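"""Bundled clone-frequency table of the Pomorie crystallizer-pond library.

The table lists the 26 archaeal OTUs recovered from crystallizer pond P18
(34% salinity) of the Pomorie salterns, Bulgaria: per-OTU clone counts,
family/genus affiliation of the closest BLAST match and its percent
identity.  It is the substrate for the sequence-free replication analysis
(diversity statistics, dominance, novelty fraction) and supplies the
default abundances and identity spectrum of the synthetic community
generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table1", "table1_counts", "STATED_TOTAL_CLONES"]

#: library size stated for the analysis (112 clones minus 3 chimeras)
STATED_TOTAL_CLONES = 109


def load_table1() -> pd.DataFrame:
    """The bundled OTU frequency table as a DataFrame (one row per OTU)."""
    with resources.files("ardra.data").joinpath("pomorie_table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["is_novel"] = df["best_match_identity_pct"] < 97
    return df


def table1_counts() -> list[int]:
    """Per-OTU clone counts in table order."""
    return load_table1()["count"].tolist()
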