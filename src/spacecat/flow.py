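"""Flow-sort purity modeling: gate false positives, expected contamination
in a sorted population, and exact enrichment tests.

The contamination model treats a sorted dataset of ``n_sorted`` cells as
gate-positive events drawn from an equal pre-sort mixture of on-target cells
(gate-positive at ``sample_positive_rate``) and off-target cells
(gate-positive at the control-measured ``background_fp_rate``), so the
expected number of off-target cells in the sorted set is
``n_sorted * background_fp_rate / sample_positive_rate``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GatePurityModel",
    "expected_contamination",
    "fisher_exact",
    "purity_report",
]


@dataclass
class GatePurityModel:
    """Gate rates and sort size for the contamination expectation.

    background_fp_rate is the gate-positive fraction of a non-photoactivated
    control; sample_positive_rate the gate-positive fraction of the tagged
    sample; abundance_ratio is off-target : on-target pre-sort abundance
    (default 1, i.e. equal abundance).
    """

    background_fp_rate: float
    sample_positive_rate: float
    n_sorted: int
    abundance_ratio: float = 1.0

    def __post_init__(self):
        if not (0 <= self.background_fp_rate <= 1
                and 0 <= self.sample_positive_rate <= 1):
            raise ValueError("rates must be in [0, 1]")
        if self.background_fp_rate > self.sample_positive_rate:
            warnings.warn(
                "background false-positive rate exceeds the sample "
                "positive rate; the contamination model is unreliable here"
            )
        if self.n_sorted < 0:
            raise ValueError("n_sorted must be non-negative")
        if self.abundance_ratio < 0:
            raise ValueError("abundance_ratio must be non-negative")


def expected_contamination(model: GatePurityModel):
    """Expected off-target cells among ``n_sorted`` sorted cells.

    Returns ``(expected_errors, rounded)``.
    """
    if model.sample_positive_rate == 0:
        raise ValueError("sample_positive_rate must be positive")
    expected = (model.n_sorted * model.abundance_ratio
                * model.background_fp_rate / model.sample_positive_rate)
    return expected, int(round(expected))


def fisher_exact(table):
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p-value uses probability ordering: with margins fixed, it
    sums hypergeometric probabilities of all tables no more probable than
    the observed one. Returns ``(odds_ratio, p_two_sided)`` with the sample
    odds ratio (ad/bc; inf when bc = 0 and ad > 0, nan for 0/0).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be integers")
    a, b, c, d = (int(v) for v in t.ravel())
    n = a + b + c + d
    r1 = a + b       # first row margin
    c1 = a + c       # first column margin
    if n == 0:
        return np.nan, 1.0

    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)

    # support of the (1,1) cell given fixed margins
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    # small relative slack so ties in probability are counted as ties
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return odds, min(p, 1.0)


def purity_report(events: pd.DataFrame, gate_column: str = "gate_positive",
                  label_column: str = "true_label",
                  background_fp_rate: float | None = None,
                  background_label: str = "background") -> pd.DataFrame:
    """Tabulate gate-positive counts and rates per population label.

    When ``background_fp_rate`` is given, the expected number of
    contaminating (background) cells among each non-background label's
    gate-positive events is appended via :func:`expected_contamination`.
    Empty input yields an empty report.
    """
    for col in (gate_column, label_column):
        if col not in events.columns:
            raise KeyError(f"events table is missing column {col!r}")
    if len(events) == 0:
        return pd.DataFrame(
            columns=["n_events", "n_positive", "positive_rate",
                     "expected_contamination"]
        )
    rows = {}
    for lbl, grp in events.groupby(label_column, sort=True):
        n = len(grp)
        pos = int(grp[gate_column].sum())
        rows[lbl] = {
            "n_events": n,
            "n_positive": pos,
            "positive_rate": pos / n,
            "expected_contamination": np.nan,
        }
    if background_fp_rate is not None:
        for lbl, row in rows.items():
            if lbl == background_label or row["positive_rate"] == 0:
                continue
            model = GatePurityModel(
                background_fp_rate=background_fp_rate,
                sample_positive_rate=row["positive_rate"],
                n_sorted=row["n_positive"],
            )
            row["expected_contamination"] = expected_contamination(model)[0]
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = label_column
    return report
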