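"""Published worked-example rank tables bundled with the package.

Two small rank tables (the twenty top-ranked probes/peaks of the public
leukemia microarray and ovarian-cancer proteomic benchmark datasets, ranked by
the three filters) ship as TSVs.  They exercise the moderation-and-summation
path end to end with published inputs and are used by the test suite and the
reproduction script; they are *inputs* to the ranker, not precomputed outputs.
"""

from __future__ import annotations

from importlib import resources

from .overall_ranker import RankTable

__all__ = ["load_leukemia_rank_table", "load_ovarian_rank_table"]


def _load(name: str) -> RankTable:
    path = resources.files("hybridfs") / "data" / name
    with resources.as_file(path) as p:
        return RankTable.from_tsv(str(p))


def load_leukemia_rank_table() -> RankTable:
    """Top-20 rank table for the leukemia (ALL/AML, 72x7129) benchmark."""
    return _load("leukemia_top20_rt.tsv")


def load_ovarian_rank_table() -> RankTable:
    """Top-20 rank table for the ovarian-cancer (253x15154) benchmark."""
    return _load("ovarian_top20_rt.tsv")
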