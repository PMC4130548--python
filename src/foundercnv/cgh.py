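"""Array-CGH copy-number genotyping.

Processing chain for two-channel CGH arrays hybridized against a single
reference genome: per-locus median summarization of probe-level signals,
validation calling on |median log2| > 0.5, hybridization QC (derivative
log ratio spread, sex concordance), the rCV polymorphism/performance
metric, integer copy-number fitting by two methods (joint log2 +
intensity, log2-only) gated by correlation against sequencing read-depth
copy numbers, and intensity-calibrated continuous copy-number estimation
for loci that do not resolve into integer states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import CN_ZERO_FLOOR

__all__ = [
    "LocusSummary",
    "HybridizationQc",
    "CopyNumberCall",
    "RcvResult",
    "MethodSelection",
    "summarize_locus",
    "summarize_probe_table",
    "call_validation",
    "compute_dlr",
    "check_sex_concordance",
    "compute_rcv",
    "fit_integer_cn",
    "select_cn_method",
    "estimate_continuous_cn",
]


@dataclass(frozen=True)
class LocusSummary:
    """Per-sample, per-locus medians of the three aCGH channels."""

    sample_id: str
    locus_id: str
    median_log2: float
    median_test: float
    median_ref: float

    def __post_init__(self) -> None:
        for v in (self.median_log2, self.median_test, self.median_ref):
            if not math.isfinite(v):
                raise ValueError("locus summary medians must be finite")


@dataclass
class HybridizationQc:
    sample_id: str
    dlr: float
    reported_sex: str
    inferred_sex: str  # male | female | unknown
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class CopyNumberCall:
    sample_id: str
    locus_id: str
    cn: float  # integer-valued for clustering methods, continuous otherwise
    method: str  # joint_fit | log2_only | intensity_calibrated
    r: float | None = None  # locus-level correlation with read-depth CN

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValueError("copy number must be >= 0")
        if self.method in ("joint_fit", "log2_only") and self.cn != round(self.cn):
            raise ValueError("clustering methods must produce integer copy numbers")
        if self.r is not None and not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation r must be in [-1, 1]")


@dataclass
class RcvResult:
    locus_id: str
    rcv: float  # may be +inf when the reference channel is invariant
    variant_and_well_performing: bool
    needs_review: bool = False


def summarize_locus(probes: pd.DataFrame) -> LocusSummary:
    """Median log2 ratio and channel intensities over all probes in a locus.

    ``probes`` holds the probe rows of one sample at one locus (columns
    ``sample``, ``locus_id``, ``log2_ratio``, ``test_intensity``,
    ``ref_intensity``).  Even probe counts use the mean-of-central-pair
    median convention (numpy's default).
    """
    if len(probes) == 0:
        raise ValueError("cannot summarize an empty probe set")
    samples = probes["sample"].unique()
    loci = probes["locus_id"].unique()
    if len(samples) != 1 or len(loci) != 1:
        raise ValueError("summarize_locus expects probes of one sample at one locus")
    if (probes["test_intensity"] <= 0).any() or (probes["ref_intensity"] <= 0).any():
        raise ValueError("intensities must be positive")
    return LocusSummary(
        sample_id=str(samples[0]),
        locus_id=str(loci[0]),
        median_log2=float(np.median(probes["log2_ratio"])),
        median_test=float(np.median(probes["test_intensity"])),
        median_ref=float(np.median(probes["ref_intensity"])),
    )


def summarize_probe_table(probe_table: pd.DataFrame) -> list[LocusSummary]:
    """Apply :func:`summarize_locus` to every (sample, locus) group."""
    return [
        summarize_locus(group)
        for _, group in probe_table.groupby(["sample", "locus_id"], sort=True)
    ]


def call_validation(summary: LocusSummary, threshold: float = 0.5) -> bool:
    """A putative CNV validates iff |median log2 ratio| strictly exceeds 0.5."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return abs(summary.median_log2) > threshold


def compute_dlr(ordered_log2: Sequence[float]) -> float:
    """Derivative log ratio spread of one hybridization.

    The SD of successive probe-to-probe log2 differences divided by
    sqrt(2) — for white probe noise of SD sigma this estimates sigma, so a
    threshold like 0.24 reads directly as a per-probe noise ceiling.
    Probes must be supplied in genomic order.
    """
    x = np.asarray(list(ordered_log2), dtype=float)
    if x.size < 2:
        raise ValueError("DLR needs at least two probes in genomic order")
    return float(np.std(np.diff(x), ddof=1) / np.sqrt(2.0))


def dlr_per_sample(probe_table: pd.DataFrame) -> pd.Series:
    """Per-sample DLR pooled over within-locus probe differences.

    On a targeted array the probe set is not copy-neutral, so successive
    differences across locus boundaries would count true copy-number
    steps as noise; differences are therefore taken within each locus
    (probes in genomic order) and pooled per sample before applying the
    spread formula.
    """
    out = {}
    for sample, group in probe_table.groupby("sample"):
        diffs = []
        for _, locus in group.sort_values("probe_start").groupby("locus_id"):
            if len(locus) >= 2:
                diffs.append(np.diff(locus["log2_ratio"].to_numpy()))
        if not diffs:
            raise ValueError(f"sample {sample}: no locus with >=2 probes")
        pooled = np.concatenate(diffs)
        out[sample] = float(np.std(pooled, ddof=1) / np.sqrt(2.0))
    return pd.Series(out, name="dlr")


_SEX_CN = {"male": 1.0, "female": 2.0}


def check_sex_concordance(
    x_chromosome_summaries: Iterable[LocusSummary],
    reported_sex: str,
    reference_sex: str = "female",
) -> tuple[str, bool | None]:
    """Infer sample sex from X-chromosome log2 ratios and compare to report.

    Against a reference of known sex the X copy ratio is 1/2, 1 or 2
    depending on the test sample's sex; the inferred sex is the candidate
    whose theoretical median X log2 is closest to the observed one.
    Returns ``(inferred_sex, concordant)``; with no X-chromosome loci the
    inferred sex is ``"unknown"`` and concordance indeterminate (None).
    """
    if reference_sex not in _SEX_CN:
        raise ValueError("reference_sex must be male or female")
    if reported_sex not in _SEX_CN:
        raise ValueError("reported_sex must be male or female")
    medians = [s.median_log2 for s in x_chromosome_summaries]
    if not medians:
        return "unknown", None
    observed = float(np.median(medians))
    ref_cn = _SEX_CN[reference_sex]
    inferred = min(
        _SEX_CN,
        key=lambda sex: abs(observed - math.log2(_SEX_CN[sex] / ref_cn)),
    )
    return inferred, inferred == reported_sex


def compute_rcv(
    summaries: Sequence[LocusSummary],
    threshold: float = 1.4,
) -> RcvResult:
    """Polymorphism/performance metric for one locus across samples.

    rCV = CV(median test intensities) / CV(median reference intensities),
    CV = SD/mean across samples.  A large rCV means the test channel
    varies while the reference channel is reproducible — a polymorphic,
    well-performing locus; the flag fires when rCV strictly exceeds the
    threshold (default 1.4).  A zero reference CV is pathological (no
    hybridization-to-hybridization variation at all) and is reported as an
    infinite sentinel flagged for review, never as a silent pass.
    """
    if len(summaries) < 3:
        raise ValueError("rCV requires summaries from at least three samples")
    loci = {s.locus_id for s in summaries}
    if len(loci) != 1:
        raise ValueError("rCV is a per-locus metric; mixed loci supplied")
    test = np.array([s.median_test for s in summaries], dtype=float)
    ref = np.array([s.median_ref for s in summaries], dtype=float)
    if (test <= 0).any() or (ref <= 0).any():
        raise ValueError("intensities must be positive")
    locus_id = summaries[0].locus_id
    cv_test = test.std(ddof=1) / test.mean()
    if ref.mean() == 0:
        raise ZeroDivisionError("zero mean reference intensity")
    cv_ref = ref.std(ddof=1) / ref.mean()
    if cv_ref == 0:
        return RcvResult(locus_id, float("inf"), False, needs_review=True)
    rcv = float(cv_test / cv_ref)
    return RcvResult(locus_id, rcv, rcv > threshold)


def _theoretical_log2(cn: np.ndarray | float, reference_cn: int) -> np.ndarray | float:
    return np.log2(np.maximum(cn, CN_ZERO_FLOOR) / reference_cn)


def fit_integer_cn(
    summaries: Sequence[LocusSummary],
    method: str = "joint_fit",
    max_cn: int = 8,
    reference_cn: int = 2,
    max_rms_residual: float = 0.2,
) -> list[CopyNumberCall] | None:
    """Cluster per-sample locus medians into integer copy-number states.

    Each sample is assigned the state c in [0, max_cn] whose theoretical
    log2 ratio log2(max(c, eps)/CN_ref) is nearest its observed median
    log2; ``joint_fit`` additionally scores the intensity channel through
    log2(median_test / median_ref), which shares the same theoretical
    value and anchors absolute copy number when the log2 channel carries a
    hybridization offset.  A free per-locus log2 offset (initialized at
    zero, so absolute anchoring defaults to the reference copy number) is
    refined by a short assign/re-estimate loop.  Returns ``None`` — the
    locus is unfittable, a state rather than an exception — when the
    root-mean-square residual of the best assignment exceeds
    ``max_rms_residual`` (data not sitting near any integer-state grid).
    """
    if method not in ("joint_fit", "log2_only"):
        raise ValueError(f"unknown method {method!r}")
    if len(summaries) < 3:
        raise ValueError("integer CN fitting requires at least three samples")
    states = np.arange(0, max_cn + 1)
    theo = _theoretical_log2(states.astype(float), reference_cn)

    x1 = np.array([s.median_log2 for s in summaries], dtype=float)
    x2 = np.log2(
        np.array([s.median_test for s in summaries], dtype=float)
        / np.array([s.median_ref for s in summaries], dtype=float)
    )

    offset = 0.0
    assign = np.zeros(len(x1), dtype=int)
    for _ in range(25):
        d = (x1[:, None] - offset - theo[None, :]) ** 2
        if method == "joint_fit":
            d = d + (x2[:, None] - theo[None, :]) ** 2
        new_assign = np.argmin(d, axis=1)
        new_offset = float(np.mean(x1 - theo[new_assign]))
        if np.array_equal(new_assign, assign) and abs(new_offset - offset) < 1e-12:
            break
        assign, offset = new_assign, new_offset

    resid = x1 - offset - theo[assign]
    if method == "joint_fit":
        resid = np.concatenate([resid, x2 - theo[assign]])
    if float(np.sqrt(np.mean(resid**2))) > max_rms_residual:
        return None
    return [
        CopyNumberCall(s.sample_id, s.locus_id, float(states[a]), method)
        for s, a in zip(summaries, assign)
    ]


@dataclass
class MethodSelection:
    """Outcome of gating the two integer-CN methods on read-depth CN."""

    calls: list[CopyNumberCall] | None
    chosen_method: str | None
    r_by_method: dict[str, float | None]
    rejected: bool
    reason: str | None = None


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def select_cn_method(
    calls_a: Sequence[CopyNumberCall],
    calls_b: Sequence[CopyNumberCall],
    readdepth_cn: dict[str, float] | pd.Series,
    r_min: float = 0.65,
) -> MethodSelection:
    """Choose between the two fitting methods by read-depth correlation.

    Pearson r is computed per method over the samples that also carry a
    sequencing read-depth copy number; the higher-r method wins (ties
    prefer ``joint_fit`` for determinism) and the locus is rejected when
    the best r falls below ``r_min`` or is undefined (zero variance in
    either vector).
    """
    rd = dict(readdepth_cn.items() if isinstance(readdepth_cn, pd.Series) else readdepth_cn.items())

    def corr(calls: Sequence[CopyNumberCall]) -> float | None:
        pairs = [(c.cn, rd[c.sample_id]) for c in calls if c.sample_id in rd]
        if len(pairs) < 3:
            return None
        arr = np.asarray(pairs, dtype=float)
        return _pearson(arr[:, 0], arr[:, 1])

    candidates: list[tuple[float, Sequence[CopyNumberCall]]] = []
    r_by_method: dict[str, float | None] = {}
    for calls in (calls_a, calls_b):
        if calls is None:
            continue
        r = corr(calls)
        r_by_method[calls[0].method] = r
        if r is not None:
            candidates.append((r, calls))
    if not candidates:
        return MethodSelection(None, None, r_by_method, True, "correlation undefined")

    def rank(item: tuple[float, Sequence[CopyNumberCall]]) -> tuple[float, int]:
        r, calls = item
        return (r, 1 if calls[0].method == "joint_fit" else 0)

    best_r, best_calls = max(candidates, key=rank)
    if best_r < r_min:
        return MethodSelection(
            None, None, r_by_method, True, f"best correlation {best_r:.3f} below {r_min}"
        )
    chosen = [
        CopyNumberCall(c.sample_id, c.locus_id, c.cn, c.method, r=best_r)
        for c in best_calls
    ]
    return MethodSelection(chosen, best_calls[0].method, r_by_method, False)


def estimate_continuous_cn(
    summaries: Sequence[LocusSummary],
    single_copy_intensity: float,
) -> list[CopyNumberCall]:
    """Intensity-calibrated continuous copy number.

    The reference sample's copy number at the locus is its median
    reference intensity divided by the signal intensity of a single copy
    (estimated from control loci of known copy number); each test sample's
    copy number is then reference CN times 2^(median log2 ratio).
    """
    if single_copy_intensity <= 0:
        raise ValueError("single_copy_intensity must be positive")
    out = []
    for s in summaries:
        if s.median_test <= 0 or s.median_ref <= 0:
            raise ValueError("intensities must be positive")
        ref_cn = s.median_ref / single_copy_intensity
        out.append(
            CopyNumberCall(
                s.sample_id,
                s.locus_id,
                float(ref_cn * 2.0**s.median_log2),
                "intensity_calibrated",
            )
        )
    return out
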