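"""Per-transcript tail summaries and differential polyadenylation testing.

The differential test fits, per transcript, an ordinary least-squares model

    log2(tail length) ~ condition + replicate

on per-read PASS estimates (Gaussian family, identity link), reports the
two-sided Wald p-value of the condition coefficient, adjusts across tested
transcripts with Benjamini–Hochberg, and flags transcripts significant when
padj < alpha, |Δmedian| ≥ min_delta_median nt and both conditions have at
least min_reads supporting reads.  Only transcripts passing the read-count
pre-filter are tested (and form the BH family).

Tail densities are Gaussian-kernel KDEs on a fixed grid, rescaled so the
maximum equals 1; the reported mode is the grid argmax (smallest tail on
ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

from .io import filter_qc_pass

__all__ = [
    "TailKDE",
    "TailSummary",
    "summarize_tails",
    "summarize_by_transcript",
    "density_table",
    "bh_adjust",
    "apply_significance_filters",
    "DifferentialTailTester",
    "test_differential_tails",
    "compare_counts",
]


class TailKDE(BaseEstimator):
    """Max-scaled Gaussian-kernel density of a tail-length sample.

    Parameters
    ----------
    bandwidth:
        "mode-stable" (default): h = σ̂·(0.75·n)^(−1/7), an oversmoothed rule
        targeting the argmax — mode estimation optimizes at the slower
        n^(−1/7) bandwidth rate, and the extra smoothing trades a small
        (≲1 nt at desk scale) upward bias on right-skewed peaks for a
        several-fold smaller argmax variance.  Also accepted: "silverman",
        "scott" (classic density-targeted rules) or a bandwidth in nt.
    grid_min, grid_max, grid_step:
        Evaluation grid in nt (default 0–350 at 0.5 nt).

    Attributes (after ``fit``)
    --------------------------
    grid_ : evaluation grid (nt)
    density_ : density rescaled so ``density_.max() == 1``
    mode_ : grid argmax; smallest grid value on exact ties
    median_ : sample median (nt)
    n_ : number of observations
    """

    def __init__(
        self,
        bandwidth: str | float = "mode-stable",
        grid_min: float = 0.0,
        grid_max: float = 350.0,
        grid_step: float = 0.5,
    ):
        self.bandwidth = bandwidth
        self.grid_min = grid_min
        self.grid_max = grid_max
        self.grid_step = grid_step

    def fit(self, X, y=None):
        tails = np.asarray(X, dtype=float).ravel()
        tails = tails[np.isfinite(tails)]
        if tails.size == 0:
            raise ValueError("cannot summarize an empty tail collection")
        self.n_ = int(tails.size)
        self.median_ = float(np.median(tails))
        self.grid_ = np.arange(
            self.grid_min, self.grid_max + self.grid_step / 2, self.grid_step
        )
        sd = float(np.std(tails))
        if sd == 0.0 or tails.size < 2:
            # Degenerate sample: a spike at the observed value.
            density = np.zeros_like(self.grid_)
            density[int(np.argmin(np.abs(self.grid_ - tails[0])))] = 1.0
            self.density_ = density
            self.mode_ = float(self.grid_[int(np.argmax(density))])
            return self
        if self.bandwidth == "mode-stable":
            h = sd * (0.75 * tails.size) ** (-1.0 / 7.0)
            kde = gaussian_kde(tails, bw_method=h / sd)
        elif isinstance(self.bandwidth, str):
            kde = gaussian_kde(tails, bw_method=self.bandwidth)
        else:
            if self.bandwidth <= 0:
                raise ValueError("numeric bandwidth must be positive")
            kde = gaussian_kde(tails, bw_method=self.bandwidth / sd)
        density = kde(self.grid_)
        peak = density.max()
        self.density_ = density / peak if peak > 0 else density
        self.mode_ = float(self.grid_[int(np.argmax(self.density_))])
        return self


@dataclass(frozen=True)
class TailSummary:
    """Summary of one tail-length collection (one transcript × condition)."""

    n: int
    median: float
    mode: float
    grid: np.ndarray
    density: np.ndarray  # scaled to a maximum of 1


def summarize_tails(tails, bandwidth: str | float = "mode-stable", **grid_kwargs) -> TailSummary:
    """Median, KDE mode and max-scaled density of a tail collection."""
    kde = TailKDE(bandwidth=bandwidth, **grid_kwargs).fit(tails)
    return TailSummary(kde.n_, kde.median_, kde.mode_, kde.grid_, kde.density_)


def summarize_by_transcript(
    records: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    bandwidth: str | float = "mode-stable",
) -> pd.DataFrame:
    """Per-(transcript, condition) summary table of PASS reads.

    With no sample sheet all reads are summarized as a single group per
    transcript (condition "all").
    """
    recs = filter_qc_pass(records)
    if samples is not None:
        recs = recs.merge(samples[["sample_id", "condition"]], on="sample_id")
    else:
        recs = recs.assign(condition="all")
    rows = []
    for (tx, cond), grp in recs.groupby(["transcript_id", "condition"], sort=True):
        s = summarize_tails(grp["polya_length"].to_numpy(), bandwidth=bandwidth)
        rows.append(
            {
                "transcript_id": tx,
                "condition": cond,
                "n": s.n,
                "median_tail": s.median,
                "mode_tail": s.mode,
            }
        )
    return pd.DataFrame(rows)


def density_table(
    records: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    bandwidth: str | float = "silverman",
    **grid_kwargs,
) -> pd.DataFrame:
    """Long-format max-scaled density curves per (transcript, condition).

    Columns: transcript_id, condition, tail, scaled_density — the export
    format behind density-distribution figures.  Uses the Silverman rule by
    default (the curve, not its argmax, is the target here).
    """
    recs = filter_qc_pass(records)
    if samples is not None:
        recs = recs.merge(samples[["sample_id", "condition"]], on="sample_id")
    else:
        recs = recs.assign(condition="all")
    parts = []
    for (tx, cond), grp in recs.groupby(["transcript_id", "condition"], sort=True):
        s = summarize_tails(
            grp["polya_length"].to_numpy(), bandwidth=bandwidth, **grid_kwargs
        )
        parts.append(
            pd.DataFrame(
                {
                    "transcript_id": tx,
                    "condition": cond,
                    "tail": s.grid,
                    "scaled_density": s.density,
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=["transcript_id", "condition", "tail", "scaled_density"]
        )
    return pd.concat(parts, ignore_index=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order.

    q(i) = min_{j >= i} p(j)·m/j over the ascending ordering, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def apply_significance_filters(
    results: pd.DataFrame,
    alpha: float = 0.05,
    min_delta_median: float = 10.0,
    min_reads: int = 20,
) -> np.ndarray:
    """Boolean significance flags from the three filters.

    A transcript is significant when p_adjusted < alpha, |delta_median| ≥
    min_delta_median (nt) and both per-condition counts (the ``n_*``
    columns) are ≥ min_reads.
    """
    n_cols = [c for c in results.columns if c.startswith("n_")]
    if len(n_cols) != 2:
        raise ValueError("expected exactly two per-condition count columns (n_*)")
    return (
        (results["p_adjusted"].to_numpy() < alpha)
        & (np.abs(results["delta_median"].to_numpy()) >= min_delta_median)
        & (results[n_cols].min(axis=1).to_numpy() >= min_reads)
    )


class DifferentialTailTester(BaseEstimator):
    """Per-transcript differential polyadenylation test.

    Parameters
    ----------
    min_reads : minimum PASS reads per condition for a transcript to be tested (default 20).
    alpha : adjusted-p significance threshold (default 0.05).
    min_delta_median : minimum |Δmedian| in nt (default 10).
    tail_floor : tails below this are floored before log2 (default 1 nt).

    ``fit(records, samples)`` expects PASS-filtered tail records and a sample
    sheet with exactly two condition levels.  Fitted attributes:

    results_ : DataFrame, one row per tested transcript, with per-condition
        counts and medians, delta_median (cond2 − cond1), the condition
        log2-fold-change coefficient, p_value, p_adjusted, significant and
        degenerate flags.
    conditions_ : (reference condition, contrast condition), in sample-sheet
        order of first appearance.
    """

    def __init__(
        self,
        min_reads: int = 20,
        alpha: float = 0.05,
        min_delta_median: float = 10.0,
        tail_floor: float = 1.0,
    ):
        self.min_reads = min_reads
        self.alpha = alpha
        self.min_delta_median = min_delta_median
        self.tail_floor = tail_floor

    def fit(self, X: pd.DataFrame, y: pd.DataFrame = None):
        records, samples = X, y
        if samples is None:
            raise ValueError("a sample sheet is required (pass as y)")
        conditions = list(dict.fromkeys(samples["condition"]))
        if len(conditions) != 2:
            raise ValueError(
                f"exactly two condition levels required, got {conditions}"
            )
        self.conditions_ = (conditions[0], conditions[1])

        df = records.merge(
            samples[["sample_id", "condition", "replicate_id"]],
            on="sample_id",
            how="left",
        )
        if df["condition"].isna().any():
            missing = df.loc[df["condition"].isna(), "sample_id"].unique().tolist()
            raise ValueError(f"records reference unknown sample_id(s): {missing}")

        df = df.assign(
            log2_tail=np.log2(np.maximum(df["polya_length"].to_numpy(), self.tail_floor)),
            is_c2=(df["condition"] == self.conditions_[1]).astype(float),
        )
        replicate_levels = list(dict.fromkeys(samples["replicate_id"]))

        rows = []
        for tx, grp in df.groupby("transcript_id", sort=True):
            n1 = int((grp["condition"] == self.conditions_[0]).sum())
            n2 = int((grp["condition"] == self.conditions_[1]).sum())
            if n1 < self.min_reads or n2 < self.min_reads:
                continue
            med1 = float(grp.loc[grp["condition"] == self.conditions_[0], "polya_length"].median())
            med2 = float(grp.loc[grp["condition"] == self.conditions_[1], "polya_length"].median())
            effect, p, degenerate = self._fit_one(grp, replicate_levels)
            rows.append(
                {
                    "transcript_id": tx,
                    f"n_{self.conditions_[0]}": n1,
                    f"n_{self.conditions_[1]}": n2,
                    f"median_{self.conditions_[0]}": med1,
                    f"median_{self.conditions_[1]}": med2,
                    "delta_median": med2 - med1,
                    "condition_effect_log2": effect,
                    "p_value": p,
                    "degenerate": degenerate,
                }
            )
        results = pd.DataFrame(rows)
        if len(results):
            results["p_adjusted"] = bh_adjust(results["p_value"].to_numpy())
            results["significant"] = apply_significance_filters(
                results, self.alpha, self.min_delta_median, self.min_reads
            )
        else:
            results["p_adjusted"] = pd.Series(dtype=float)
            results["significant"] = pd.Series(dtype=bool)
        self.results_ = results
        return self

    def _fit_one(self, grp: pd.DataFrame, replicate_levels: list[str]):
        y = grp["log2_tail"].to_numpy()
        if np.unique(grp["polya_length"].to_numpy()).size < 2:
            return 0.0, 1.0, True
        cols = [np.ones(len(grp)), grp["is_c2"].to_numpy()]
        # Replicate encoded as treatment contrasts vs the first level; levels
        # absent from this transcript's reads drop out of the design.
        present = [r for r in replicate_levels if (grp["replicate_id"] == r).any()]
        for rep in present[1:]:
            cols.append((grp["replicate_id"] == rep).to_numpy(dtype=float))
        Xd = np.column_stack(cols)
        res = sm.OLS(y, Xd).fit()
        effect = float(res.params[1])
        p = float(res.pvalues[1])
        if not np.isfinite(p):
            return effect, 1.0, True
        return effect, min(max(p, np.finfo(float).tiny), 1.0), False


def test_differential_tails(
    records: pd.DataFrame,
    samples: pd.DataFrame,
    min_reads: int = 20,
    alpha: float = 0.05,
    min_delta_median: float = 10.0,
    tail_floor: float = 1.0,
) -> pd.DataFrame:
    """Functional wrapper around :class:`DifferentialTailTester`."""
    tester = DifferentialTailTester(
        min_reads=min_reads,
        alpha=alpha,
        min_delta_median=min_delta_median,
        tail_floor=tail_floor,
    )
    return tester.fit(records, samples).results_


def compare_counts(records: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Raw PASS read counts per transcript per condition (scatter export).

    No test is attached; transcripts absent from a condition count 0.
    """
    recs = filter_qc_pass(records).merge(
        samples[["sample_id", "condition"]], on="sample_id"
    )
    if recs.empty:
        return pd.DataFrame(columns=["transcript_id"])
    table = (
        recs.groupby(["transcript_id", "condition"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    table.columns = [f"count_{c}" for c in table.columns]
    return table.reset_index().rename_axis(None, axis=1)
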