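"""Readers and writers for haplotypes, maps, matrices and run reports.

Haplotypes come either as a plain TSV (one row per haplotype: sample id,
haplotype index 1/2, then one 0/1 column per SNP) or as a phased VCF.
Allele orientation is harmonized so that 1 codes the major allele across
the input sample; the flips are recorded so genotype coding stays
consistent downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .covariance import CM_PER_BP, GeneticMap

__all__ = [
    "HaplotypeData",
    "read_haplotypes",
    "read_map",
    "write_haplotypes_tsv",
    "write_map_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_report",
]


@dataclass
class HaplotypeData:
    """Binary haplotype matrix (2 rows per sample) with bookkeeping."""

    matrix: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    flipped: np.ndarray  # SNPs re-oriented to major-allele coding

    def diplotypes(self) -> tuple[np.ndarray, np.ndarray]:
        return self.matrix[0::2], self.matrix[1::2]


def _orient(matrix: np.ndarray, harmonize: bool) -> tuple[np.ndarray, np.ndarray]:
    if not harmonize:
        return matrix, np.zeros(matrix.shape[1], bool)
    from .covariance import orient_major

    return orient_major(matrix)


def read_haplotypes(
    path: str | Path,
    fmt: str | None = None,
    sample_ids: list[str] | None = None,
    harmonize_major: bool = True,
) -> HaplotypeData:
    """Read phased haplotypes from TSV or VCF.

    Parameters
    ----------
    path
        Input file.  Format is inferred from the suffix unless ``fmt`` is
        one of ``"tsv"`` or ``"vcf"``.
    sample_ids
        Optional subset (and ordering) of samples to load.
    harmonize_major
        Recode each SNP so allele 1 is the major allele of the loaded
        sample; flipped SNPs are reported in the result.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "tsv"
    if fmt == "tsv":
        return _read_haplotypes_tsv(path, sample_ids, harmonize_major)
    if fmt == "vcf":
        return _read_haplotypes_vcf(path, sample_ids, harmonize_major)
    raise ValueError(f"unknown haplotype format {fmt!r}")


def _read_haplotypes_tsv(path: Path, sample_ids, harmonize: bool) -> HaplotypeData:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col, hap_col = df.columns[0], df.columns[1]
    snp_ids = list(df.columns[2:])
    available = list(dict.fromkeys(df[id_col]))
    if sample_ids is None:
        sample_ids = available
    missing = [s for s in sample_ids if s not in available]
    if missing:
        raise ValueError(
            f"sample id(s) {missing} not in {path.name}; available: {available}"
        )
    rows = []
    for s in sample_ids:
        sub = df[df[id_col] == s].sort_values(hap_col)
        if len(sub) != 2:
            raise ValueError(f"sample {s!r} must have exactly 2 haplotype rows")
        rows.append(sub.iloc[0, 2:].to_numpy(dtype=np.int8))
        rows.append(sub.iloc[1, 2:].to_numpy(dtype=np.int8))
    M = np.vstack(rows)
    if not np.all(np.isin(M, [0, 1])):
        raise ValueError("haplotype entries must be 0/1")
    M, flipped = _orient(M, harmonize)
    return HaplotypeData(M, list(sample_ids), snp_ids, flipped)


def _read_haplotypes_vcf(path: Path, sample_ids, harmonize: bool) -> HaplotypeData:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    available = list(vcf.samples)
    if sample_ids is None:
        sample_ids = available
    missing = [s for s in sample_ids if s not in available]
    if missing:
        raise ValueError(
            f"sample id(s) {missing} not in {path.name}; available: {available}"
        )
    cols = [available.index(s) for s in sample_ids]
    snp_ids, h1_rows, h2_rows = [], [], []
    for var in vcf:
        gts = var.genotypes  # [allele1, allele2, phased] per sample
        a1, a2 = [], []
        for c in cols:
            g = gts[c]
            if len(g) != 3:
                raise ValueError(
                    f"ploidy != 2 at {var.CHROM}:{var.POS} for sample "
                    f"{sample_ids[cols.index(c)]!r}"
                )
            if not g[2]:
                raise ValueError(
                    f"unphased genotype at {var.CHROM}:{var.POS} "
                    f"(record {var.ID or var.POS}); phase the VCF first"
                )
            a1.append(g[0])
            a2.append(g[1])
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        h1_rows.append(a1)
        h2_rows.append(a2)
    vcf.close()
    h1 = np.asarray(h1_rows, np.int8).T  # samples x snps
    h2 = np.asarray(h2_rows, np.int8).T
    M = np.empty((2 * len(sample_ids), h1.shape[1]), np.int8)
    M[0::2] = h1
    M[1::2] = h2
    # VCF codes ALT as 1; re-orient to major allele if requested
    M, flipped = _orient(M, harmonize)
    return HaplotypeData(M, list(sample_ids), snp_ids, flipped)


def read_map(path: str | Path) -> GeneticMap:
    """Genetic map TSV with columns snp_id [chr] position_bp [position_cM].

    When cM positions are absent they are derived from bp at 1 cM per Mbp.
    """
    df = pd.read_csv(path, sep="\t")
    if "snp_id" not in df.columns:
        raise ValueError("map file needs a 'snp_id' column")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id {dup!r} in map")
    bp = df["position_bp"].to_numpy() if "position_bp" in df.columns else None
    cm = df["position_cM"].to_numpy(float) if "position_cM" in df.columns else None
    if cm is None and bp is None:
        raise ValueError("map needs position_bp and/or position_cM")
    if cm is None:
        cm = bp.astype(float) * CM_PER_BP
    if np.any(np.diff(cm) < 0):
        raise ValueError("map positions must be sorted")
    return GeneticMap(list(df["snp_id"]), cm, bp)


def write_haplotypes_tsv(path: str | Path, data: HaplotypeData | None = None, *,
                         matrix: np.ndarray | None = None,
                         sample_ids=None, snp_ids=None) -> None:
    if data is not None:
        matrix, sample_ids, snp_ids = data.matrix, data.sample_ids, data.snp_ids
    n_samples = matrix.shape[0] // 2
    recs = []
    for i in range(n_samples):
        for h in (0, 1):
            recs.append([sample_ids[i], h + 1, *matrix[2 * i + h].tolist()])
    df = pd.DataFrame(recs, columns=["sample_id", "haplotype", *snp_ids])
    df.to_csv(path, sep="\t", index=False)


def write_map_tsv(path: str | Path, gmap: GeneticMap, chrom: str = "1") -> None:
    df = pd.DataFrame(
        {
            "snp_id": list(gmap.snp_ids),
            "chr": chrom,
            "position_bp": (
                gmap.position_bp
                if gmap.position_bp is not None
                else np.round(gmap.position_cM / CM_PER_BP).astype(int)
            ),
            "position_cM": gmap.position_cM,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_matrix_tsv(path: str | Path, M: np.ndarray, snp_ids) -> None:
    pd.DataFrame(M, index=list(snp_ids), columns=list(snp_ids)).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), list(df.columns)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if obj is None or isinstance(obj, (str, int, bool)):
        return obj
    if isinstance(obj, float):
        return obj
    return str(obj)


def write_report(path: str | Path, payload: dict, seed: int | None = None) -> None:
    """Deterministic JSON report including the seed and package version.

    Sample-size failure states are serialized as the explicit string
    ``"> n_max"`` rather than a number.
    """
    from . import __version__

    def encode_failures(obj):
        if isinstance(obj, dict):
            return {
                k: ("> n_max" if v is None and str(k).startswith(("n_opt", "median_n_opt", "n_single"))
                    else encode_failures(v))
                for k, v in obj.items()
            }
        if isinstance(obj, list):
            return [encode_failures(v) for v in obj]
        return obj

    doc = {"hspower_version": __version__, "seed": seed}
    doc.update(encode_failures(_jsonable(payload)))
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
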