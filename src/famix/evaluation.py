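"""Recovery evaluation: posterior estimates against known diets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DietEstimationResults

__all__ = ["RecoveryReport", "compare_to_truth", "rank_sources"]


@dataclass
class RecoveryReport:
    """Per-(level, source) recovery table with aggregate accuracy measures.

    The point estimate is the posterior median; the interval is the central
    95% credible interval. Errors are in percentage points of diet share.
    """

    table: pd.DataFrame
    mean_absolute_error: float
    max_error: float
    coverage: float

    def __str__(self):
        return (
            f"diet recovery: MAE {self.mean_absolute_error:.1f} pp, "
            f"max error {self.max_error:.1f} pp, "
            f"95% CI coverage {self.coverage:.2f}\n"
            + self.table.to_string(index=False)
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _truth_as_dict(truth, levels, source_names):
    if isinstance(truth, dict) and not any(isinstance(v, dict) for v in truth.values()):
        truth = {lev: truth for lev in levels}
    if not isinstance(truth, dict):
        arr = np.asarray(truth, dtype=float)
        truth = {lev: dict(zip(source_names, arr)) for lev in levels}
    out = {}
    for lev in levels:
        if lev not in truth:
            raise KeyError(f"no truth given for level {lev!r}")
        t = truth[lev]
        if not isinstance(t, dict):
            t = dict(zip(source_names, np.asarray(t, dtype=float)))
        missing = set(source_names) ^ set(t)
        if missing:
            raise KeyError(f"truth/source mismatch at level {lev!r}: {sorted(missing)}")
        out[lev] = t
    return out


def compare_to_truth(results: DietEstimationResults, truth) -> RecoveryReport:
    """Compare posterior diet proportions with known proportions.

    ``truth`` may be a proportions vector (applied to all factor levels), a
    source->proportion mapping, or a level -> (source -> proportion) mapping.
    """
    levels = results.levels
    sources = results.source_names
    truth = _truth_as_dict(truth, levels, sources)
    rows = []
    for lev in levels:
        P = results.p_draws(lev)
        med = np.median(P, axis=0)
        lo, hi = np.percentile(P, [2.5, 97.5], axis=0)
        for k, src in enumerate(sources):
            t = float(truth[lev][src])
            rows.append(
                {
                    "level": lev,
                    "source": src,
                    "true": t,
                    "median": med[k],
                    "abs_error_pp": 100.0 * abs(med[k] - t),
                    "ci_low": lo[k],
                    "ci_high": hi[k],
                    "inside_95ci": bool(lo[k] <= t <= hi[k]),
                }
            )
    table = pd.DataFrame(rows)
    return RecoveryReport(
        table=table,
        mean_absolute_error=float(table["abs_error_pp"].mean()),
        max_error=float(table["abs_error_pp"].max()),
        coverage=float(table["inside_95ci"].mean()),
    )


def rank_sources(
    results: DietEstimationResults, level: str | None = None
) -> pd.DataFrame:
    """Sources ordered by posterior median diet share (descending; ties broken
    by source name). The last row — the minimum — is flagged: in a Bayesian
    mixing model no proportion is exactly zero, so an absent source shows up
    as the smallest, strictly positive share."""
    med = results.median(level)
    order = sorted(med, key=lambda s: (-med[s], s))
    df = pd.DataFrame(
        {
            "source": order,
            "median": [med[s] for s in order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    df["is_minimum"] = df["rank"] == len(order)
    return df
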