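"""Candidate-selection and variant filter cascades.

Two families of rules live here.  The CNV side screens read-depth copy
numbers of a small set of sequenced study genomes against a reference
panel: a non-variant band, rank-sum group comparisons and per-sample
z-score outliers.  The SNV/indel side implements the gene-disruptive
discovery filter (class, case-specificity, rarity) and the set-inclusion
rules feeding the transcript-level rare-variant association test
(functional class, conservation, continental-panel frequency,
missingness).

All filters are pure and idempotent; excluded records are reported with
reason codes rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantRecord",
    "ReadDepthCnMatrix",
    "CandidateDecision",
    "FunctionalClass",
    "GENE_DISRUPTIVE_CLASSES",
    "classify_nonvariant_locus",
    "select_readdepth_candidates",
    "filter_gene_disruptive",
    "select_set_variants",
]

#: Functional consequence vocabulary used throughout.
FunctionalClass = (
    "nonsense",
    "splice_site",
    "missense",
    "frameshift_indel",
    "inframe_indel",
    "synonymous",
    "other",
)

GENE_DISRUPTIVE_CLASSES = frozenset({"nonsense", "splice_site", "frameshift_indel"})
_CODING_INDEL_CLASSES = frozenset({"frameshift_indel", "inframe_indel"})
_PROTEIN_ALTERING = frozenset(
    {"missense", "nonsense", "splice_site", "frameshift_indel", "inframe_indel"}
)


@dataclass
class VariantRecord:
    """Annotated sequence variant (1-based VCF position convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    functional_class: str
    gerp: float | None
    panel_afs: dict[str, float]
    known_variant: bool
    genotypes: dict[str, int | None]
    transcript_id: str
    vid: str = ""

    def __post_init__(self) -> None:
        if self.functional_class not in FunctionalClass:
            raise ValueError(f"unknown functional class {self.functional_class!r}")
        for panel, af in self.panel_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"panel AF out of [0,1] for {panel}: {af}")
        if not self.vid:
            self.vid = f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def missingness(self) -> float:
        if not self.genotypes:
            return 0.0
        n_missing = sum(1 for g in self.genotypes.values() if g is None)
        return n_missing / len(self.genotypes)

    def carriers(self, sample_ids: Iterable[str]) -> list[str]:
        """Samples among ``sample_ids`` carrying >=1 alternate allele.

        Missing genotypes count as non-carrier (recorded as a caveat by
        the calling filter, not here).
        """
        out = []
        for sid in sample_ids:
            g = self.genotypes.get(sid)
            if g is not None and g > 0:
                out.append(sid)
        return out


@dataclass
class ReadDepthCnMatrix:
    """Per-locus, per-sample read-depth copy numbers with group labels.

    ``copy_number`` is loci x samples; ``groups`` maps each sample to
    one of case / control / reference_panel.
    """

    copy_number: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if (self.copy_number.to_numpy() < 0).any():
            raise ValueError("copy numbers must be >= 0")
        unknown = set(self.groups.unique()) - {"case", "control", "reference_panel"}
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.copy_number.columns if self.groups.get(s) == group]


@dataclass
class CandidateDecision:
    locus_id: str
    decision: str  # nonvariant | group_difference | single_outlier | both_groups_shifted | not_selected
    statistics: dict = field(default_factory=dict)

    @property
    def selected(self) -> bool:
        return self.decision in ("group_difference", "single_outlier", "both_groups_shifted")


def classify_nonvariant_locus(
    cn_values: Sequence[float], band: tuple[float, float] = (1.5, 2.5)
) -> bool:
    """True iff every study copy number lies strictly inside the open band.

    Loci whose study samples all sit in (1.5, 2.5) are diploid-invariant
    and carry no genotypable signal.
    """
    values = np.asarray(list(cn_values), dtype=float)
    if values.size == 0:
        raise ValueError("at least one copy-number value required")
    lo, hi = band
    return bool(np.all((values > lo) & (values < hi)))


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small untied samples,
    tie-corrected normal approximation otherwise (scipy's 'auto' policy)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


def select_readdepth_candidates(
    matrix: ReadDepthCnMatrix,
    band: tuple[float, float] = (1.5, 2.5),
    p_strong: float = 0.01,
    p_weak: float = 0.1,
    z_threshold: float = 2.0,
) -> list[CandidateDecision]:
    """Screen read-depth copy numbers of study genomes against a panel.

    Per locus, after the non-variant band screen, a locus is selected when
    (a) both study groups are shifted against the panel (rank-sum p <=
    ``p_strong`` in one group and p < ``p_weak`` in the other, in either
    assignment), (b) either group alone differs at p <= ``p_strong``, or
    (c) any single study sample is a |z| > ``z_threshold`` outlier against
    the panel copy-number distribution.  The most specific rule that fires
    labels the decision; every computed statistic is recorded for audit.
    """
    panel_ids = matrix.samples_in("reference_panel")
    if not panel_ids:
        raise ValueError("reference panel group is empty")
    case_ids = matrix.samples_in("case")
    control_ids = matrix.samples_in("control")
    study_ids = case_ids + control_ids

    decisions = []
    for locus_id, row in matrix.copy_number.iterrows():
        panel = row[panel_ids].to_numpy(dtype=float)
        study = row[study_ids].to_numpy(dtype=float)
        stats_d: dict = {}

        if classify_nonvariant_locus(study, band=band):
            decisions.append(CandidateDecision(str(locus_id), "nonvariant", stats_d))
            continue

        p_case = p_ctrl = None
        if case_ids:
            p_case = _rank_sum_p(row[case_ids].to_numpy(dtype=float), panel)
            stats_d["p_case_vs_panel"] = p_case
        else:
            stats_d["p_case_vs_panel_skipped"] = "empty case group"
        if control_ids:
            p_ctrl = _rank_sum_p(row[control_ids].to_numpy(dtype=float), panel)
            stats_d["p_control_vs_panel"] = p_ctrl
        else:
            stats_d["p_control_vs_panel_skipped"] = "empty control group"

        mu, sd = panel.mean(), panel.std(ddof=1)
        z = (study - mu) / sd if sd > 0 else np.full_like(study, np.nan)
        stats_d["max_abs_z"] = float(np.nanmax(np.abs(z))) if len(z) else float("nan")

        # "both shifted": strong evidence in one group AND at least weak in
        # the other; either assignment of the two thresholds may fire and
        # the one that did is recorded.
        both = False
        if p_case is not None and p_ctrl is not None:
            if p_case <= p_strong and p_ctrl < p_weak:
                both = True
                stats_d["both_assignment"] = "strong=case, weak=control"
            elif p_ctrl <= p_strong and p_case < p_weak:
                both = True
                stats_d["both_assignment"] = "strong=control, weak=case"

        if both:
            decision = "both_groups_shifted"
        elif (p_case is not None and p_case <= p_strong) or (
            p_ctrl is not None and p_ctrl <= p_strong
        ):
            decision = "group_difference"
        elif sd > 0 and np.nanmax(np.abs(z)) > z_threshold:
            decision = "single_outlier"
        else:
            decision = "not_selected"
        decisions.append(CandidateDecision(str(locus_id), decision, stats_d))
    return decisions


def filter_gene_disruptive(
    records: Iterable[VariantRecord],
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    af_max: float = 0.05,
    audit: list | None = None,
) -> list[VariantRecord]:
    """Gene-disruptive discovery filter.

    Retains variants that are (i) nonsense, splice-site or frameshifting,
    (ii) carried by at least one case and by no sequenced control, and
    (iii) rare (allele frequency < ``af_max`` in every annotated reference
    panel) or absent from the known-variant database.  Missing genotypes
    are treated as non-carrier for the case-only rule; records carrying a
    missing case or control genotype are flagged in the audit log.
    Records missing required annotation are excluded with a reason code.
    """
    if set(case_ids) & set(control_ids):
        raise ValueError("case and control id sets must be disjoint")
    kept = []
    for rec in records:
        if rec.functional_class not in GENE_DISRUPTIVE_CLASSES:
            _log(audit, rec, "class_not_gene_disruptive")
            continue
        if not rec.carriers(case_ids):
            _log(audit, rec, "no_case_carrier")
            continue
        if rec.carriers(control_ids):
            _log(audit, rec, "carried_by_control")
            continue
        rare = all(af < af_max for af in rec.panel_afs.values()) if rec.panel_afs else None
        if rare is None and rec.known_variant:
            _log(audit, rec, "missing_panel_af_annotation")
            continue
        if not (rare or not rec.known_variant):
            _log(audit, rec, "common_and_known")
            continue
        if any(rec.genotypes.get(s) is None for s in list(case_ids) + list(control_ids)):
            _log(audit, rec, "kept_with_missing_genotypes_caveat")
        kept.append(rec)
    return kept


def select_set_variants(
    records: Iterable[VariantRecord],
    transcript: str,
    gerp_min: float = 3.0,
    af_max: float = 0.05,
    missingness_max: float = 0.15,
    mode: str = "rare_conserved",
    audit: list | None = None,
) -> list[VariantRecord]:
    """Set-inclusion rules for the transcript-level rare-variant test.

    ``all_protein_altering`` keeps missense, nonsense, splice-site and
    coding indels.  ``rare_conserved`` keeps nonsense and coding indels
    plus missense/splice-site variants with GERP strictly above
    ``gerp_min``; all retained variants must additionally be rare
    (AF < ``af_max``) in every annotated continental panel.  Both modes
    drop variants with missingness strictly above ``missingness_max``.
    """
    if mode not in ("all_protein_altering", "rare_conserved"):
        raise ValueError(f"unknown mode {mode!r}")
    kept = []
    for rec in records:
        if rec.transcript_id != transcript:
            _log(audit, rec, "other_transcript")
            continue
        if rec.missingness > missingness_max:
            _log(audit, rec, "missingness_above_threshold")
            continue
        if mode == "all_protein_altering":
            if rec.functional_class not in _PROTEIN_ALTERING:
                _log(audit, rec, "not_protein_altering")
                continue
        else:
            if rec.functional_class in {"nonsense"} | _CODING_INDEL_CLASSES:
                pass
            elif rec.functional_class in ("missense", "splice_site"):
                if rec.gerp is None:
                    _log(audit, rec, "missing_gerp_annotation")
                    continue
                if not rec.gerp > gerp_min:
                    _log(audit, rec, "gerp_not_above_threshold")
                    continue
            else:
                _log(audit, rec, "class_not_eligible")
                continue
            if not rec.panel_afs:
                _log(audit, rec, "missing_panel_af_annotation")
                continue
            if not all(af < af_max for af in rec.panel_afs.values()):
                _log(audit, rec, "common_in_reference_panel")
                continue
        kept.append(rec)
    return kept


def _log(audit: list | None, rec: VariantRecord, reason: str) -> None:
    if audit is not None:
        audit.append((rec.vid, reason))
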