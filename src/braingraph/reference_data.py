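"""Published reference values bundled with the package.

These small CSVs hold summary statistics printed in the published
structural-connectome sex-difference analysis of the HCP 500-Subjects
release (96 subjects, 52 female / 44 male) that this package re-implements.
They are used as *inputs* for arithmetic checks — re-running the
Holm-Bonferroni correction on the published round-2 p-value column, and the
female/male ratio report on the published group means — not as expected
outputs of any simulation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["published_two_round_table", "published_sum_means"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("braingraph.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def published_two_round_table() -> pd.DataFrame:
    """The published ranked two-round results (149 hypotheses).

    Columns: ``scale`` (parcellation resolution label as printed),
    ``attribute`` (``Scope_Property_Weight``), ``p_round1``, ``p_round2``,
    ``p_corrected`` (uncapped Holm products, 5 decimals).
    """
    return _load("published_two_round_table.csv")


def published_sum_means() -> pd.DataFrame:
    """Published whole-graph edge-sum group means used by the artifact check.

    Columns: ``scale``, ``attribute``, ``mean_F``, ``mean_M``, ``p``,
    ``fm_ratio`` as printed.
    """
    return _load("published_sum_means.csv")
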