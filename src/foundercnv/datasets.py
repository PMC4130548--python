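"""Worked-example inputs.

Two kinds of small, fully-enumerated inputs live here: the published
multi-cohort replication table for the intronic *NEDD4L* deletion
(cohort sizes and carrier-allele frequencies as printed, from which
integer allele counts are recovered), and hand-built variant fixtures
whose pass/fail status under each filter cascade is known by
enumeration.  These drive the worked examples in the analysis scripts
and the oracle tests.
"""

from __future__ import annotations

import pandas as pd

from .filters import VariantRecord
from .simulate import StratumTable

__all__ = [
    "replication_table",
    "replication_strata",
    "gene_disruptive_fixture",
    "set_inclusion_fixture",
]

# Published replication of the intronic deletion: five case-control
# cohorts with deletion-allele frequencies as printed (two of them with a
# zero control frequency, hence infinite per-stratum odds ratios).
_REPLICATION_ROWS = [
    # study, ancestry, n_cases, n_controls, case_freq, control_freq
    ("Chicago", "European American", 177, 219, 0.014, 0.000),
    ("Freiburg", "German", 370, 364, 0.015, 0.015),
    ("COAST", "European American", 189, 172, 0.019, 0.015),
    ("GALAII", "Puerto Rican", 755, 742, 0.001, 0.000),
    ("SAGE", "African American", 1052, 747, 0.004, 0.003),
]


def replication_table() -> pd.DataFrame:
    """The replication cohorts as a data frame (frequencies as printed)."""
    return pd.DataFrame(
        _REPLICATION_ROWS,
        columns=["study", "ancestry", "n_cases", "n_controls", "case_freq", "control_freq"],
    )


def replication_strata() -> list[StratumTable]:
    """Replication cohorts as 2x2 allele-count strata.

    Integer carrier-allele counts are recovered from the printed
    frequencies by rounding ``freq * 2N`` to the nearest integer — the
    only reconstruction consistent with the printed per-stratum odds
    ratios (e.g. the German cohort's 0.98 arises from 11/740 vs 11/728
    alleles, not from the equal rounded frequencies).
    """
    strata = []
    for study, _, n_ca, n_co, f_ca, f_co in _REPLICATION_ROWS:
        a = round(f_ca * 2 * n_ca)
        c = round(f_co * 2 * n_co)
        strata.append(
            StratumTable(
                label=study,
                case_carrier=a,
                case_noncarrier=2 * n_ca - a,
                control_carrier=c,
                control_noncarrier=2 * n_co - c,
            )
        )
    return strata


# ---------------------------------------------------------------------------
# Hand-enumerated filter fixtures
# ---------------------------------------------------------------------------

_FIXTURE_CASES = ["C1", "C2"]
_FIXTURE_CONTROLS = ["U1", "U2"]


def _rec(vid, vclass, *, gerp=None, afs=None, known=True, geno=None,
         transcript="TX1", pos=1000) -> VariantRecord:
    return VariantRecord(
        chrom="chr1",
        pos=pos,
        ref="A",
        alt="T",
        vid=vid,
        functional_class=vclass,
        gerp=gerp,
        panel_afs={} if afs is None else afs,
        known_variant=known,
        genotypes=geno or {},
        transcript_id=transcript,
    )


def gene_disruptive_fixture() -> tuple[list[VariantRecord], list[str], list[str], set[str]]:
    """Ten hand-built records for the gene-disruptive discovery filter.

    Exactly three qualify (case-only, disruptive class, rare-or-novel):
    ``gd01`` (rare known nonsense), ``gd07`` (common but novel
    frameshift) and ``gd08`` (rare known splice-site).  Returns
    ``(records, case_ids, control_ids, expected_passing_vids)``.
    """
    case_only = {"C1": 1, "C2": 0, "U1": 0, "U2": 0}
    nobody = {"C1": 0, "C2": 0, "U1": 0, "U2": 0}
    both = {"C1": 1, "C2": 0, "U1": 1, "U2": 0}
    control_only = {"C1": 0, "C2": 0, "U1": 0, "U2": 1}
    rare = {"pilot": 0.01}
    common = {"pilot": 0.20}
    records = [
        _rec("gd01", "nonsense", afs=rare, known=True, geno=dict(case_only), pos=100),
        _rec("gd02", "synonymous", afs=rare, known=True, geno=dict(case_only), pos=200),
        _rec("gd03", "missense", gerp=5.0, afs=rare, known=True, geno=dict(case_only), pos=300),
        _rec("gd04", "nonsense", afs=rare, known=True, geno=dict(nobody), pos=400),
        _rec("gd05", "splice_site", afs=rare, known=True, geno=dict(both), pos=500),
        _rec("gd06", "nonsense", afs=common, known=True, geno=dict(case_only), pos=600),
        _rec("gd07", "frameshift_indel", afs=common, known=False, geno=dict(case_only), pos=700),
        _rec("gd08", "splice_site", afs={"pilot": 0.04}, known=True, geno=dict(case_only), pos=800),
        _rec("gd09", "frameshift_indel", afs=rare, known=True, geno=dict(control_only), pos=900),
        _rec("gd10", "nonsense", afs=None, known=True, geno=dict(case_only), pos=1000),
    ]
    return records, _FIXTURE_CASES, _FIXTURE_CONTROLS, {"gd01", "gd07", "gd08"}


def set_inclusion_fixture() -> tuple[list[VariantRecord], set[str]]:
    """Twelve hand-built records for the rare-conserved set-inclusion rule.

    Exactly six qualify for transcript TX1 in ``rare_conserved`` mode:
    nonsense (``sv01``), frameshift (``sv02``), inframe indel at exactly
    15% missingness (``sv03``, boundary kept), conserved missense
    (``sv04``), conserved splice-site (``sv05``) and a missense just
    under the 5% panel-frequency ceiling (``sv06``).  The exclusions
    exercise the strict GERP > 3 boundary (2.9 and exactly 3.0), 16%
    missingness, a 6% continental-panel frequency, a synonymous class
    and a wrong-transcript record.  Returns ``(records, expected_vids)``.
    """
    samples = [f"S{k:03d}" for k in range(100)]

    def geno(n_missing: int) -> dict:
        g = {s: 0 for s in samples}
        g[samples[0]] = 1
        for s in samples[1 : 1 + n_missing]:
            g[s] = None
        return g

    rare = {"AMR": 0.01, "AFR": 0.02, "EUR": 0.001}
    records = [
        _rec("sv01", "nonsense", afs=dict(rare), geno=geno(0), pos=100),
        _rec("sv02", "frameshift_indel", afs={"AMR": 0.04, "AFR": 0.0, "EUR": 0.0}, geno=geno(0), pos=200),
        _rec("sv03", "inframe_indel", afs=dict(rare), geno=geno(15), pos=300),
        _rec("sv04", "missense", gerp=5.2, afs=dict(rare), geno=geno(0), pos=400),
        _rec("sv05", "splice_site", gerp=3.5, afs=dict(rare), geno=geno(0), pos=500),
        _rec("sv06", "missense", gerp=8.0, afs={"AMR": 0.049, "AFR": 0.049, "EUR": 0.049}, geno=geno(0), pos=600),
        _rec("sv07", "missense", gerp=2.9, afs=dict(rare), geno=geno(0), pos=700),
        _rec("sv08", "missense", gerp=3.0, afs=dict(rare), geno=geno(0), pos=800),
        _rec("sv09", "nonsense", afs=dict(rare), geno=geno(16), pos=900),
        _rec("sv10", "nonsense", afs={"AMR": 0.01, "AFR": 0.01, "EUR": 0.06}, geno=geno(0), pos=1000),
        _rec("sv11", "synonymous", afs=dict(rare), geno=geno(0), pos=1100),
        _rec("sv12", "missense", gerp=6.0, afs=dict(rare), geno=geno(0), transcript="TX2", pos=1200),
    ]
    return records, {"sv01", "sv02", "sv03", "sv04", "sv05", "sv06"}
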