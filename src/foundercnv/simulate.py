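"""Synthetic founder-population data generators.

Everything downstream of this module (array-CGH genotyping, candidate
selection, association testing) is exercised on data produced here: a
multi-generation pedigree descended from a small founder pool, biallelic
CNV alleles dropped through it, probe-level two-channel aCGH signals over
integer copy-number states, stratified case-control carrier tables, and
annotated variant tables with the structure the filter cascades assume.

All generators draw from named per-component RNG streams derived from one
global integer seed, so adding a generator never shifts the draws of an
existing one, and every output is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .filters import VariantRecord

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "SimulatedCnvTruth",
    "StratumTable",
    "simulate_pedigree",
    "compute_kinship",
    "drop_biallelic_genotypes",
    "assign_phenotypes",
    "simulate_cnv_truth",
    "simulate_acgh_probes",
    "simulate_strata",
    "simulate_variant_table",
]

#: Copy-number floor used when forming log2 ratios for homozygous deletions
#: (copy number 0).  Arrays saturate rather than report -inf; 0.05 copies
#: gives a large negative but finite theoretical log2 ratio (~ -5.3 against
#: a two-copy reference).
CN_ZERO_FLOOR = 0.05


class PedigreeError(ValueError):
    """Structural problem in a pedigree (missing parent, cycle, bad sex)."""


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named RNG stream: one global seed, independent per-component streams."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Pedigree and kinship
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None
    mother: str | None
    sex: str  # "male" | "female"
    generation: int

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """Ordered collection of individuals; founders first, parents before children."""

    individuals: list[Individual]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def ids(self) -> list[str]:
        return [ind.iid for ind in self.individuals]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        return self._index()[iid]

    def _index(self) -> dict[str, Individual]:
        return {ind.iid: ind for ind in self.individuals}

    def validate(self) -> None:
        index = self._index()
        if len(index) != len(self.individuals):
            raise PedigreeError("duplicate individual ids")
        for ind in self.individuals:
            if ind.sex not in ("male", "female"):
                raise PedigreeError(f"{ind.iid}: sex must be male/female, got {ind.sex!r}")
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(f"{ind.iid}: non-founders need exactly two parents")
            if ind.father is not None:
                for pid in (ind.father, ind.mother):
                    if pid not in index:
                        raise PedigreeError(f"{ind.iid}: unknown parent {pid!r}")
                    if index[pid].generation >= ind.generation:
                        raise PedigreeError(
                            f"{ind.iid}: parent {pid} not in an earlier generation"
                        )
                if index[ind.father].sex != "male" or index[ind.mother].sex != "female":
                    raise PedigreeError(f"{ind.iid}: parents must be of opposite sex")

    def topo_order(self) -> list[Individual]:
        """Individuals sorted by generation (parents always precede children)."""
        return sorted(self.individuals, key=lambda ind: (ind.generation, ind.iid))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iid": [i.iid for i in self.individuals],
                "father": [i.father or "0" for i in self.individuals],
                "mother": [i.mother or "0" for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "generation": [i.generation for i in self.individuals],
            }
        )


@dataclass
class KinshipMatrix:
    """Pairwise kinship coefficients phi_ij over pedigree members.

    The diagonal stores phi_ii = (1 + f_i) / 2 with f_i the inbreeding
    coefficient, so 2 * matrix is the additive relationship matrix.
    """

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("kinship matrix shape does not match ids")

    def phi(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.matrix[i, j])

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        pos = {s: k for k, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return KinshipMatrix(list(ids), self.matrix[np.ix_(idx, idx)])


def compute_kinship(pedigree: Pedigree) -> KinshipMatrix:
    """Recursive pedigree kinship.

    phi(i,i) = (1 + phi(father_i, mother_i)) / 2, phi(i,j) =
    (phi(father_i, j) + phi(mother_i, j)) / 2 for i later in topological
    order than j; founders are mutually unrelated with phi = 1/2 on the
    diagonal.
    """
    order = pedigree.topo_order()
    ids = [ind.iid for ind in order]
    pos = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    for i, ind in enumerate(order):
        if ind.is_founder:
            phi[i, i] = 0.5
            continue
        fa, mo = pos[ind.father], pos[ind.mother]
        phi[i, i] = 0.5 * (1.0 + phi[fa, mo])
        for j in range(i):
            val = 0.5 * (phi[fa, j] + phi[mo, j])
            phi[i, j] = phi[j, i] = val
    # return in the pedigree's own ordering
    back = np.array([pos[iid] for iid in pedigree.ids])
    return KinshipMatrix(pedigree.ids, phi[np.ix_(back, back)])


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    offspring_rate: float = 3.0,
    seed: int = 0,
) -> Pedigree:
    """Simulate a founder-population pedigree.

    Mating model: random monogamous pairing within a generation with
    Poisson offspring counts (mean ``2 * offspring_rate`` per couple, so
    the population grows roughly by ``offspring_rate`` per generation).
    Pairings between close kin (kinship >= 1/4, i.e. sib-sib or closer)
    are avoided, which lets inbreeding accumulate through cousin matings
    the way it does in a real closed founder population.  The default
    offspring rate reflects the large sibships of high-fertility founder
    communities (~6 children per couple).

    ``n_generations`` counts total generations including the founders:
    ``n_generations=1`` returns exactly the founders.
    """
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if offspring_rate <= 0:
        raise ValueError("offspring_rate must be positive")
    rng = _stream(seed, "pedigree")

    individuals: list[Individual] = [
        Individual(
            iid=f"G0_{k:04d}",
            father=None,
            mother=None,
            sex="male" if k % 2 == 0 else "female",
            generation=0,
        )
        for k in range(n_founders)
    ]

    for g in range(1, n_generations):
        # kinship among current members, used only for mate avoidance
        phi = compute_kinship(Pedigree(list(individuals)))
        pos = {iid: k for k, iid in enumerate(phi.ids)}
        prev = [ind for ind in individuals if ind.generation == g - 1]
        males = [ind for ind in prev if ind.sex == "male"]
        females = [ind for ind in prev if ind.sex == "female"]
        rng.shuffle(males)
        rng.shuffle(females)
        children: list[Individual] = []
        used: set[str] = set()
        k_child = 0
        for m in males:
            partner = None
            for f in females:
                if f.iid in used:
                    continue
                if phi.matrix[pos[m.iid], pos[f.iid]] >= 0.25:
                    continue  # avoid sib-sib / parent-offspring matings
                partner = f
                break
            if partner is None:
                continue
            used.add(partner.iid)
            n_off = rng.poisson(2.0 * offspring_rate)
            for _ in range(n_off):
                children.append(
                    Individual(
                        iid=f"G{g}_{k_child:04d}",
                        father=m.iid,
                        mother=partner.iid,
                        sex="male" if rng.random() < 0.5 else "female",
                        generation=g,
                    )
                )
                k_child += 1
        individuals.extend(children)
        if not children:
            break  # lineage died out; return what exists

    return Pedigree(individuals)


# ---------------------------------------------------------------------------
# Gene dropping and phenotypes
# ---------------------------------------------------------------------------


def drop_haplotypes(
    pedigree: Pedigree,
    founder_sampler,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Drop per-haplotype values through the pedigree.

    Founders receive two values from ``founder_sampler(rng)``; every child
    inherits one randomly chosen haplotype value from each parent.  Returns
    a DataFrame indexed by individual id with columns ``hap_pat``/``hap_mat``.
    """
    values: dict[str, tuple] = {}
    for ind in pedigree.topo_order():
        if ind.is_founder:
            values[ind.iid] = (founder_sampler(rng), founder_sampler(rng))
        else:
            pat = values[ind.father][int(rng.integers(2))]
            mat = values[ind.mother][int(rng.integers(2))]
            values[ind.iid] = (pat, mat)
    out = pd.DataFrame.from_dict(values, orient="index", columns=["hap_pat", "hap_mat"])
    return out.loc[pedigree.ids]


def drop_biallelic_genotypes(
    pedigree: Pedigree,
    founder_allele_freq: float,
    seed: int = 0,
    return_haplotypes: bool = False,
):
    """Drop a biallelic variant through the pedigree; returns 0/1/2 counts.

    Founder haplotypes carry the allele with probability
    ``founder_allele_freq``; each child inherits one random haplotype per
    parent (Mendelian segregation).  With ``return_haplotypes=True`` the
    per-haplotype table is returned alongside, which makes Mendelian
    consistency directly checkable.
    """
    if not 0.0 <= founder_allele_freq <= 1.0:
        raise ValueError("founder_allele_freq must be in [0, 1]")
    rng = _stream(seed, "genedrop")
    haps = drop_haplotypes(
        pedigree, lambda r: int(r.random() < founder_allele_freq), rng
    )
    counts = (haps["hap_pat"] + haps["hap_mat"]).astype(int)
    counts.name = "allele_count"
    if return_haplotypes:
        return counts, haps
    return counts


def assign_phenotypes(
    pedigree: Pedigree,
    risk_genotypes: pd.Series,
    baseline_prevalence: float,
    per_allele_or: float,
    seed: int = 0,
    familial_sd: float = 1.8,
    kinship: KinshipMatrix | None = None,
    unknown_fraction: float = 0.0,
) -> pd.Series:
    """Assign asthma/control labels under a logistic liability model.

    The linear predictor is ``logit(prevalence) + log(OR) * (g - mean(g))
    + a`` where ``a`` is a kinship-structured familial liability,
    ``a ~ N(0, familial_sd^2 * 2 * Phi)``.  The familial term models the
    heritable, polygenic component of a trait like asthma: with the
    default ``familial_sd = 1.8`` the liability-scale heritability is
    about 0.5 (logistic residual variance pi^2 / 3).  Set
    ``familial_sd=0`` for i.i.d. phenotypes.  ``per_allele_or = 1`` makes
    the phenotype independent of the tested genotype regardless of the
    familial term.
    """
    if not 0.0 < baseline_prevalence < 1.0:
        raise ValueError("baseline_prevalence must be in (0, 1)")
    if per_allele_or <= 0:
        raise ValueError("per_allele_or must be positive")
    rng = _stream(seed, "phenotype")
    g = np.asarray(risk_genotypes.loc[pedigree.ids], dtype=float)
    eta = np.log(baseline_prevalence / (1 - baseline_prevalence)) + np.log(
        per_allele_or
    ) * (g - g.mean())
    if familial_sd > 0:
        if kinship is None:
            kinship = compute_kinship(pedigree)
        rel = 2.0 * kinship.subset(pedigree.ids).matrix
        chol = np.linalg.cholesky(rel + 1e-9 * np.eye(len(rel)))
        eta = eta + familial_sd * chol @ rng.standard_normal(len(rel))
    p_case = 1.0 / (1.0 + np.exp(-eta))
    labels = np.where(rng.random(len(p_case)) < p_case, "asthma", "control")
    if unknown_fraction > 0:
        mask = rng.random(len(labels)) < unknown_fraction
        labels = np.where(mask, "unknown", labels)
    return pd.Series(labels, index=pedigree.ids, name="phenotype")


# ---------------------------------------------------------------------------
# CNV truth and aCGH probe signals
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCnvTruth:
    """Ground-truth copy numbers behind a simulated aCGH experiment.

    ``loci`` has columns locus_id, chrom, start, end, allele_type,
    founder_freq; ``copy_number`` is a samples x loci integer matrix.
    """

    loci: pd.DataFrame
    copy_number: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.copy_number.to_numpy() < 0).any():
            raise ValueError("true copy numbers must be >= 0")


_ALLELE_COPIES = {
    # per-haplotype copy counts for the non-reference vs reference allele
    "deletion": (0, 1),
    "duplication": (2, 1),
}


def simulate_cnv_truth(
    pedigree: Pedigree,
    n_loci: int = 1,
    allele_type: str = "deletion",
    founder_allele_freq: float = 0.3,
    seed: int = 0,
    locus_size: int = 5000,
    multiallelic_copies: Sequence[int] = (0, 1, 2, 3),
    multiallelic_probs: Sequence[float] | None = None,
) -> SimulatedCnvTruth:
    """Drop CNV alleles through the pedigree to produce true copy numbers.

    Biallelic deletions/duplications segregate a single non-reference
    allele at the given founder frequency (CN in {0,1,2} for deletions).
    ``multiallelic`` loci segregate per-haplotype copy counts drawn from
    ``multiallelic_copies``, yielding CN distributions like the complex
    CNPs that only continuous copy-number estimation can genotype.
    """
    rng = _stream(seed, "cnvtruth")
    cols = {}
    rows = []
    for k in range(n_loci):
        locus_id = f"CNV{k:04d}"
        if allele_type in _ALLELE_COPIES:
            alt, ref = _ALLELE_COPIES[allele_type]
            sampler = lambda r: alt if r.random() < founder_allele_freq else ref
        elif allele_type == "multiallelic":
            copies = list(multiallelic_copies)
            probs = multiallelic_probs
            sampler = lambda r: int(r.choice(copies, p=probs))
        else:
            raise ValueError(f"unknown allele_type {allele_type!r}")
        haps = drop_haplotypes(pedigree, sampler, rng)
        cols[locus_id] = (haps["hap_pat"] + haps["hap_mat"]).astype(int)
        start = 1_000_000 + k * 2 * locus_size
        rows.append(
            {
                "locus_id": locus_id,
                "chrom": "chr1",
                "start": start,
                "end": start + locus_size,
                "allele_type": allele_type,
                "founder_freq": founder_allele_freq,
            }
        )
    return SimulatedCnvTruth(
        loci=pd.DataFrame(rows), copy_number=pd.DataFrame(cols, index=pedigree.ids)
    )


def simulate_acgh_probes(
    truth: SimulatedCnvTruth,
    probes_per_locus: int = 10,
    noise_sd: float = 0.15,
    reference_cn: int = 2,
    intensity_scale: float = 1000.0,
    seed: int = 0,
    log2_bias: float = 0.0,
) -> pd.DataFrame:
    """Simulate probe-level two-channel aCGH measurements.

    Per probe: ``log2_ratio = log2(max(CN, eps) / CN_ref) + N(0, sd)``,
    ``test_intensity = scale * max(CN, eps)/2 * exp(N(0, sd))`` and
    ``reference_intensity = scale * CN_ref/2 * exp(N(0, sd))`` with
    ``eps = 0.05`` copies as the zero-copy floor.  ``log2_bias`` adds a
    constant hybridization offset to the log2 channel only, emulating the
    dye/wash artifacts that break absolute anchoring of log2-only
    genotyping.  The default ``noise_sd = 0.15`` is a mid-range
    probe-level log2 SD for two-color CGH arrays and is configurable.
    """
    if probes_per_locus < 1:
        raise ValueError("probes_per_locus must be >= 1")
    if reference_cn < 1:
        raise ValueError("reference_cn must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _stream(seed, "acgh")
    loci = truth.loci.set_index("locus_id")
    samples = list(truth.copy_number.index)
    n_s, n_l, n_p = len(samples), len(loci), probes_per_locus

    cn = truth.copy_number[loci.index].to_numpy(dtype=float)
    cn_eff = np.maximum(cn, CN_ZERO_FLOOR)
    theo_log2 = np.log2(cn_eff / reference_cn) + log2_bias

    noise_l = rng.normal(0.0, noise_sd, size=(n_s, n_l, n_p)) if noise_sd else np.zeros((n_s, n_l, n_p))
    noise_t = rng.normal(0.0, noise_sd, size=(n_s, n_l, n_p)) if noise_sd else np.zeros((n_s, n_l, n_p))
    noise_r = rng.normal(0.0, noise_sd, size=(n_s, n_l, n_p)) if noise_sd else np.zeros((n_s, n_l, n_p))

    log2r = theo_log2[:, :, None] + noise_l
    test_i = intensity_scale * (cn_eff / 2.0)[:, :, None] * np.exp(noise_t)
    ref_i = intensity_scale * (reference_cn / 2.0) * np.exp(noise_r)

    starts = loci["start"].to_numpy()
    ends = loci["end"].to_numpy()
    spacing = np.maximum((ends - starts) // max(n_p, 1), 1)
    probe_start = starts[:, None] + spacing[:, None] * np.arange(n_p)

    idx_s, idx_l, idx_p = np.meshgrid(
        np.arange(n_s), np.arange(n_l), np.arange(n_p), indexing="ij"
    )
    return pd.DataFrame(
        {
            "sample": np.array(samples)[idx_s.ravel()],
            "locus_id": loci.index.to_numpy()[idx_l.ravel()],
            "chrom": loci["chrom"].to_numpy()[idx_l.ravel()],
            "probe_start": probe_start[idx_l.ravel(), idx_p.ravel()],
            "log2_ratio": log2r.ravel(),
            "test_intensity": test_i.ravel(),
            "ref_intensity": ref_i.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# Stratified replication tables and annotated variant tables
# ---------------------------------------------------------------------------


@dataclass
class StratumTable:
    """2x2 allele-count table for one replication stratum.

    Cells count carrier vs non-carrier *alleles* among cases and controls.
    """

    label: str
    case_carrier: int
    case_noncarrier: int
    control_carrier: int
    control_noncarrier: int

    def __post_init__(self) -> None:
        for v in (
            self.case_carrier,
            self.case_noncarrier,
            self.control_carrier,
            self.control_noncarrier,
        ):
            if v < 0:
                raise ValueError("counts must be non-negative")

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [
                [self.case_carrier, self.case_noncarrier],
                [self.control_carrier, self.control_noncarrier],
            ],
            dtype=float,
        )

    @property
    def case_freq(self) -> float:
        n = self.case_carrier + self.case_noncarrier
        return self.case_carrier / n if n else float("nan")

    @property
    def control_freq(self) -> float:
        n = self.control_carrier + self.control_noncarrier
        return self.control_carrier / n if n else float("nan")


def simulate_strata(
    strata_spec: Iterable[tuple],
    seed: int = 0,
) -> list[StratumTable]:
    """Draw binomial allele-count tables for stratified replication cohorts.

    ``strata_spec`` rows are ``(n_cases, n_controls, case_allele_freq,
    control_allele_freq)`` or ``(label, n_cases, n_controls, f_case,
    f_ctrl)``; counts are drawn as Binomial(2N, f) carrier alleles.
    """
    rng = _stream(seed, "strata")
    out = []
    for k, row in enumerate(strata_spec):
        row = tuple(row)
        if len(row) == 5:
            label, n_ca, n_co, f_ca, f_co = row
        elif len(row) == 4:
            label = f"stratum{k}"
            n_ca, n_co, f_ca, f_co = row
        else:
            raise ValueError("stratum spec must have 4 or 5 fields")
        if not (0 <= f_ca <= 1 and 0 <= f_co <= 1):
            raise ValueError("allele frequencies must be in [0, 1]")
        a = int(rng.binomial(2 * n_ca, f_ca))
        c = int(rng.binomial(2 * n_co, f_co))
        out.append(
            StratumTable(
                label=str(label),
                case_carrier=a,
                case_noncarrier=2 * n_ca - a,
                control_carrier=c,
                control_noncarrier=2 * n_co - c,
            )
        )
    return out


_DEFAULT_CLASS_MIX = {
    "missense": 0.50,
    "synonymous": 0.25,
    "nonsense": 0.05,
    "splice_site": 0.10,
    "frameshift_indel": 0.10,
}

_QUALIFYING_ALWAYS = {"nonsense", "frameshift_indel", "inframe_indel"}
_QUALIFYING_IF_CONSERVED = {"missense", "splice_site"}


def simulate_variant_table(
    n_variants: int,
    n_cases: int,
    n_controls: int,
    class_mix: dict[str, float] | None = None,
    gerp_params: tuple[float, float] = (1.0, 2.0),
    panel_af_params: tuple[float, float] = (0.2, 30.0),
    missingness_rate: float = 0.02,
    seed: int = 0,
    control_enrichment: float = 1.0,
    base_allele_freq: float = 0.002,
    gerp_min: float = 3.0,
    panels: Sequence[str] = ("AMR", "AFR", "EUR"),
    transcript_id: str = "TX1",
) -> tuple[list[VariantRecord], list[str], list[str]]:
    """Simulate an annotated resequencing variant table for one transcript.

    Functional classes follow ``class_mix``; GERP scores are
    Normal(``gerp_params``); continental-panel allele frequencies are
    Beta(``panel_af_params``), which makes most variants rare with an
    occasional common one that the AF < 0.05 filter removes.  Genotypes
    are Binomial(2, f) with per-group allele frequencies: *qualifying*
    variants (gene-disruptive class, or missense/splice with
    GERP > ``gerp_min``) carry ``base_allele_freq`` in cases and
    ``control_enrichment`` times that in controls, so a known carrier
    enrichment can be planted for power studies; non-qualifying variants
    have equal frequencies.  Each genotype is missing independently with
    probability ``missingness_rate``.
    """
    mix = dict(class_mix or _DEFAULT_CLASS_MIX)
    classes = list(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    if not 0.0 <= missingness_rate <= 1.0:
        raise ValueError("missingness_rate must be in [0, 1]")
    rng = _stream(seed, "variants")

    case_ids = [f"CASE{k:04d}" for k in range(n_cases)]
    control_ids = [f"CTRL{k:04d}" for k in range(n_controls)]
    records: list[VariantRecord] = []
    for v in range(n_variants):
        vclass = classes[int(rng.choice(len(classes), p=probs))]
        gerp = float(rng.normal(*gerp_params))
        afs = {p: float(rng.beta(*panel_af_params)) for p in panels}
        qualifying = vclass in _QUALIFYING_ALWAYS or (
            vclass in _QUALIFYING_IF_CONSERVED and gerp > gerp_min
        )
        f_case = base_allele_freq
        f_ctrl = min(base_allele_freq * control_enrichment, 0.5) if qualifying else f_case
        geno: dict[str, int | None] = {}
        for sid in case_ids:
            geno[sid] = None if rng.random() < missingness_rate else int(rng.binomial(2, f_case))
        for sid in control_ids:
            geno[sid] = None if rng.random() < missingness_rate else int(rng.binomial(2, f_ctrl))
        records.append(
            VariantRecord(
                chrom="chr19",
                pos=14_030_000 + v * 50,
                ref="A",
                alt="T" if "indel" not in vclass else "TA",
                vid=f"var{v:04d}",
                functional_class=vclass,
                gerp=gerp,
                panel_afs=afs,
                known_variant=bool(rng.random() < 0.5),
                genotypes=geno,
                transcript_id=transcript_id,
            )
        )
    return records, case_ids, control_ids
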