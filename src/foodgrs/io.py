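"""File formats: genotypes (VCF or dosage TSV), cohort/FFQ CSV, scores.

Genotype VCFs are parsed with cyvcf2; only GT fields are used.  Dosages are
counted against the panel's risk allele: a record whose REF/ALT orientation
is flipped relative to the panel is re-oriented, a record whose alleles do
not match the panel at all is an error naming the rsID, and panel entries
with strand-ambiguous allele pairs (A/T, C/G) trigger a warning because
orientation cannot be verified.  Multi-allelic records are rejected.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError
from .grs_engine import GenotypeMatrix, SNPPanel

_GT_TYPE_TO_ALT_DOSAGE = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}


def read_genotypes(
    path: str | Path,
    panel: SNPPanel,
    fmt: str | None = None,
) -> GenotypeMatrix:
    """Read genotypes as risk-allele dosages against a panel.

    ``fmt`` is 'vcf' or 'tsv'; inferred from the file suffix when omitted.
    Sample order is preserved.  Only panel rsIDs are kept.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "vcf":
        return _read_vcf(path, panel)
    if fmt == "tsv":
        return read_dosage_tsv(path, panel)
    raise ConfigurationError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path, panel: SNPPanel) -> GenotypeMatrix:
    from cyvcf2 import VCF

    ambiguous = set(panel.ambiguous_rsids())
    if ambiguous:
        warnings.warn(
            "panel contains strand-ambiguous (A/T or C/G) entries; allele "
            f"orientation cannot be verified for: {sorted(ambiguous)}",
            UserWarning,
            stacklevel=2,
        )
    entries = panel.entries.set_index("rsid")
    wanted = set(panel.rsids)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    mismatched: list[str] = []
    for v in vcf:
        rsid = v.ID
        if rsid not in wanted:
            continue
        if rsid in columns:
            raise FormatError(f"rsID present twice in VCF: {rsid}")
        if len(v.ALT) != 1:
            raise FormatError(f"multi-allelic record rejected: {rsid}")
        ref, alt = v.REF, v.ALT[0]
        risk = entries.loc[rsid, "risk_allele"]
        other = entries.loc[rsid, "other_allele"]
        alt_dosage = np.array(
            [_GT_TYPE_TO_ALT_DOSAGE[t] for t in v.gt_types], dtype=float
        )
        if (ref, alt) == (other, risk):
            columns[rsid] = alt_dosage
        elif (ref, alt) == (risk, other):
            columns[rsid] = 2.0 - alt_dosage
        else:
            mismatched.append(rsid)
    if mismatched:
        raise FormatError(
            "VCF alleles do not match panel risk/other alleles for: "
            f"{mismatched}"
        )
    absent = [r for r in panel.rsids if r not in columns]
    if absent:
        raise ConfigurationError(f"panel rsID(s) absent from VCF: {absent}")
    dosage = pd.DataFrame(
        {r: columns[r] for r in panel.rsids},
        index=pd.Index(samples, name="individual_id"),
    )
    return GenotypeMatrix(dosage)


def write_vcf(
    genotypes: GenotypeMatrix, panel: SNPPanel, path: str | Path
) -> None:
    """Write a minimal GT-only VCF (one contig, synthetic positions).

    Risk allele is written as ALT, other allele as REF; dosage d maps to
    GT 0/0, 0/1, 1/1 (missing -> ./.).  Output is byte-deterministic (no
    date header).
    """
    entries = panel.entries.set_index("rsid")
    samples = genotypes.individual_ids
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for j, rsid in enumerate(genotypes.rsids):
        if rsid not in entries.index:
            raise ConfigurationError(f"rsID {rsid} not in panel")
        ref = entries.loc[rsid, "other_allele"]
        alt = entries.loc[rsid, "risk_allele"]
        gts = [
            "./." if np.isnan(d) else gt_map[float(d)]
            for d in genotypes.dosage[rsid].to_numpy(dtype=float)
        ]
        lines.append(
            f"1\t{1000 * (j + 1)}\t{rsid}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_dosage_tsv(path: str | Path, panel: SNPPanel | None = None) -> GenotypeMatrix:
    """Read a dosage TSV (rows: individuals, columns: rsIDs, NA = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "individual_id"
    gm = GenotypeMatrix(df.astype(float))
    if panel is not None:
        absent = [r for r in panel.rsids if r not in set(gm.rsids)]
        if absent:
            raise ConfigurationError(
                f"panel rsID(s) absent from dosage table: {absent}"
            )
    return gm


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    genotypes.dosage.to_csv(path, sep="\t", na_rep="NA")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort/phenotype CSV indexed by individual_id."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "individual_id"
    return df


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path)
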