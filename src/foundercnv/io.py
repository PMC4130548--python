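"""Readers and writers for the pipeline's text formats.

Formats: PED (pedigree, whitespace-delimited), BED3+ (CNV loci, 0-based
half-open), VCF (annotated variants, 1-based; read back through cyvcf2),
and tab-delimited tables for probes, kinship matrices, covariates,
replication strata and association results.  Coordinate-convention
conversions are centralized here: BED intervals are 0-based half-open,
VCF positions 1-based, and no stage code performs its own +-1 arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .filters import VariantRecord
from .simulate import Individual, KinshipMatrix, Pedigree, StratumTable


class ParseError(ValueError):
    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path, self.line_no = path, line_no


# ---------------------------------------------------------------------------
# Coordinate conventions
# ---------------------------------------------------------------------------


def bed_interval_to_vcf_pos(start: int) -> int:
    """First base of a 0-based half-open BED interval in 1-based VCF terms."""
    return start + 1


def vcf_pos_to_bed_start(pos: int) -> int:
    return pos - 1


# ---------------------------------------------------------------------------
# PED pedigrees
# ---------------------------------------------------------------------------

_PED_SEX = {"1": "male", "2": "female"}
_PED_SEX_INV = {"male": "1", "female": "2"}
_PED_PHENO = {"2": "asthma", "1": "control", "0": "unknown", "-9": "unknown"}
_PED_PHENO_INV = {"asthma": "2", "control": "1", "unknown": "0", "BHR_or_symptoms": "0"}


def write_ped(pedigree: Pedigree, path, phenotypes: pd.Series | None = None,
              family: str = "FAM1") -> None:
    lines = []
    for ind in pedigree.individuals:
        pheno = "0"
        if phenotypes is not None and ind.iid in phenotypes.index:
            pheno = _PED_PHENO_INV.get(str(phenotypes[ind.iid]), "0")
        lines.append(
            "\t".join(
                [family, ind.iid, ind.father or "0", ind.mother or "0",
                 _PED_SEX_INV[ind.sex], pheno]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ped(path) -> tuple[Pedigree, pd.Series]:
    """Parse a PED file into a Pedigree plus a phenotype Series.

    Generations (absent from PED) are reconstructed as pedigree depth:
    founders at 0, children one past their deepest parent.
    """
    rows = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ParseError(path, line_no, f"expected >=6 PED fields, got {len(fields)}")
        fam, iid, father, mother, sex, pheno = fields[:6]
        if sex not in _PED_SEX:
            raise ParseError(path, line_no, f"bad sex code {sex!r}")
        rows.append((iid, father, mother, _PED_SEX[sex], _PED_PHENO.get(pheno, "unknown")))

    depth: dict[str, int] = {}
    parents = {iid: (fa, mo) for iid, fa, mo, _, _ in rows}

    def get_depth(iid: str, seen=()) -> int:
        if iid in depth:
            return depth[iid]
        if iid in seen:
            raise ParseError(path, 0, f"pedigree cycle involving {iid}")
        fa, mo = parents.get(iid, ("0", "0"))
        if fa == "0" or fa not in parents:
            depth[iid] = 0
        else:
            depth[iid] = 1 + max(get_depth(fa, seen + (iid,)), get_depth(mo, seen + (iid,)))
        return depth[iid]

    individuals = []
    pheno_map = {}
    for iid, fa, mo, sex, pheno in rows:
        founder = fa == "0" or fa not in parents
        individuals.append(
            Individual(
                iid=iid,
                father=None if founder else fa,
                mother=None if founder else mo,
                sex=sex,
                generation=get_depth(iid),
            )
        )
        pheno_map[iid] = pheno
    return Pedigree(individuals), pd.Series(pheno_map, name="phenotype")


# ---------------------------------------------------------------------------
# BED CNV loci
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CnvLocus:
    """CNV locus in 0-based half-open BED coordinates."""

    chrom: str
    start: int
    end: int
    locus_id: str
    svtype: str = "del"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.locus_id}: start must be < end (0-based half-open)")

    @property
    def length(self) -> int:
        return self.end - self.start


def write_bed(loci: Iterable[CnvLocus], path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\t{loc.svtype}\n")


def read_bed(path) -> list[CnvLocus]:
    loci = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(path, line_no, "BED needs >=3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as err:
            raise ParseError(path, line_no, f"non-integer coordinate: {err}") from None
        if start >= end:
            raise ParseError(path, line_no, f"start {start} >= end {end}")
        loci.append(
            CnvLocus(
                chrom=fields[0],
                start=start,
                end=end,
                locus_id=fields[3] if len(fields) > 3 else f"{fields[0]}:{start}-{end}",
                svtype=fields[4] if len(fields) > 4 else "del",
            )
        )
    return loci


# ---------------------------------------------------------------------------
# Tab-delimited tables
# ---------------------------------------------------------------------------

PROBE_COLUMNS = [
    "sample", "locus_id", "chrom", "probe_start",
    "log2_ratio", "test_intensity", "ref_intensity",
]


def write_probe_table(probes: pd.DataFrame, path) -> None:
    probes[PROBE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"probe table missing columns {sorted(missing)}")
    return df[PROBE_COLUMNS]


def write_kinship(kinship: KinshipMatrix, path) -> None:
    pd.DataFrame(kinship.matrix, index=kinship.ids, columns=kinship.ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(path, 1, "kinship matrix rows and columns disagree")
    return KinshipMatrix(list(df.index), df.to_numpy(dtype=float))


def write_strata(strata: Sequence[StratumTable], path) -> None:
    pd.DataFrame(
        {
            "stratum": [s.label for s in strata],
            "case_carrier": [s.case_carrier for s in strata],
            "case_noncarrier": [s.case_noncarrier for s in strata],
            "control_carrier": [s.control_carrier for s in strata],
            "control_noncarrier": [s.control_noncarrier for s in strata],
        }
    ).to_csv(path, sep="\t", index=False)


def read_strata(path) -> list[StratumTable]:
    df = pd.read_csv(path, sep="\t")
    return [
        StratumTable(
            label=str(r["stratum"]),
            case_carrier=int(r["case_carrier"]),
            case_noncarrier=int(r["case_noncarrier"]),
            control_carrier=int(r["control_carrier"]),
            control_noncarrier=int(r["control_noncarrier"]),
        )
        for _, r in df.iterrows()
    ]


def write_covariates(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, sep="\t", index_label="sample", float_format="%.10g")


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


# ---------------------------------------------------------------------------
# VCF variant tables
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CLASS,Number=1,Type=String,Description="Functional class">
##INFO=<ID=GERP,Number=1,Type=Float,Description="GERP conservation score">
##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript id">
##INFO=<ID=DB,Number=0,Type=Flag,Description="Present in known-variant database">
{af_lines}
"""

_GT = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def write_vcf(records: Sequence[VariantRecord], sample_ids: Sequence[str], path) -> None:
    """Write annotated variants as plain-text VCF with the INFO keys the
    filter cascades consume (CLASS, GERP, AF_<panel>, DB, TRANSCRIPT)."""
    panels = sorted({p for rec in records for p in rec.panel_afs})
    af_lines = "\n".join(
        f'##INFO=<ID=AF_{p},Number=1,Type=Float,Description="Allele frequency in {p} panel">'
        for p in panels
    )
    contigs = sorted({rec.chrom for rec in records})
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(af_lines=af_lines) if panels
                 else _VCF_HEADER.format(af_lines="").replace("\n\n", "\n"))
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info = [f"CLASS={rec.functional_class}", f"TRANSCRIPT={rec.transcript_id}"]
            if rec.gerp is not None:
                info.append(f"GERP={rec.gerp:.4g}")
            for p, af in sorted(rec.panel_afs.items()):
                info.append(f"AF_{p}={af:.6g}")
            if rec.known_variant:
                info.append("DB")
            gts = "\t".join(_GT[rec.genotypes.get(s)] for s in sample_ids)
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.vid}\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
                f"{';'.join(info)}\tGT\t{gts}\n"
            )


def read_vcf(path) -> tuple[list[VariantRecord], list[str]]:
    """Read annotated variants through cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    records = []
    for var in vcf:
        afs = {}
        for key, value in var.INFO:
            if key.startswith("AF_"):
                afs[key[3:]] = float(value)
        gt_types = var.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        genotypes: dict[str, int | None] = {}
        for sid, gt in zip(sample_ids, gt_types):
            genotypes[sid] = {0: 0, 1: 1, 3: 2}.get(int(gt))
        gerp = var.INFO.get("GERP")
        records.append(
            VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0] if var.ALT else ".",
                vid=var.ID or "",
                functional_class=var.INFO.get("CLASS"),
                gerp=float(gerp) if gerp is not None else None,
                panel_afs=afs,
                known_variant=var.INFO.get("DB") is not None,
                genotypes=genotypes,
                transcript_id=var.INFO.get("TRANSCRIPT") or "",
            )
        )
    return records, sample_ids


# ---------------------------------------------------------------------------
# Association result tables
# ---------------------------------------------------------------------------


def results_to_frame(results: Sequence) -> pd.DataFrame:
    def fmt_or(v):
        if v is None:
            return ""
        if v != v:  # NaN
            return "NA"
        return "Inf" if np.isinf(v) else f"{v:.6g}"

    df = pd.DataFrame(
        {
            "target": [r.target_id for r in results],
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p_value for r in results],
            "OR": [fmt_or(r.odds_ratio) for r in results],
            "case_freq": [r.case_freq for r in results],
            "control_freq": [r.control_freq for r in results],
            "tail": [r.tail for r in results],
        }
    )
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def write_results(results: Sequence, path, header_comment: str | None = None) -> None:
    df = results_to_frame(results)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
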