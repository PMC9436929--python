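"""Readers and writers for the on-disk formats.

Expression matrices travel as a 10x-style MTX triplet (``matrix.mtx`` with
genes as rows and cells as columns, ``features.tsv``, ``barcodes.tsv``)
plus a ``cell_meta.tsv`` with the per-cell metadata.  Variant evidence
travels as a TSV with one row per (cell, site, allele, UMI).

Expected evidence TSV columns (the shape a converter should produce from a
Mutect2-style per-cell VCF plus a UMI-tagged BAM):

    cell_id  donor_id  chrom  pos  ref  alt  tlod  exome_depth
    umi  alt_reads  total_reads
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy.sparse import csr_matrix

from .mutations import VariantEvidence

logger = logging.getLogger(__name__)

META_COLUMNS = [
    "donor_id", "visit_id", "age_years", "sex", "group_id", "subset",
    "total_umi", "mito_frac",
]

EVIDENCE_COLUMNS = [
    "cell_id", "donor_id", "chrom", "pos", "ref", "alt", "tlod",
    "exome_depth", "umi", "alt_reads", "total_reads",
]


def write_matrix(adata: ad.AnnData, outdir) -> None:
    """Write an expression matrix as MTX triplet + metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not hasattr(X, "tocoo"):
        X = csr_matrix(np.asarray(X))
    spio.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo(), field="integer")
    pd.Series(adata.var_names).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    cols = [c for c in META_COLUMNS if c in adata.obs.columns]
    extra = [c for c in ("true_cell_age",) if c in adata.obs.columns]
    meta = adata.obs[cols + extra].copy()
    meta.index.name = "cell_id"
    meta.to_csv(outdir / "cell_meta.tsv", sep="\t")


def read_matrix(indir) -> ad.AnnData:
    """Read an MTX triplet + metadata TSV back into an AnnData (raw)."""
    indir = Path(indir)
    M = spio.mmread(str(indir / "matrix.mtx")).tocsr().T.tocsr()
    genes = pd.read_csv(
        indir / "features.tsv", sep="\t", header=None
    )[0].astype(str)
    cells = pd.read_csv(
        indir / "barcodes.tsv", sep="\t", header=None
    )[0].astype(str)
    meta = pd.read_csv(indir / "cell_meta.tsv", sep="\t", index_col="cell_id")
    meta = meta.loc[cells]
    adata = ad.AnnData(
        X=M.astype(np.int64),
        obs=meta,
        var=pd.DataFrame(index=genes),
    )
    adata.uns["normalized"] = False
    return adata


# ---------------------------------------------------------------------------
# variant evidence
# ---------------------------------------------------------------------------


def evidence_to_frame(evidence) -> pd.DataFrame:
    rows = []
    for ev in evidence:
        for umi, alt_reads, total_reads in ev.umi_support:
            rows.append(
                (
                    ev.cell_id, ev.donor_id, ev.chrom, ev.pos, ev.ref,
                    ev.alt, ev.tlod, ev.exome_depth, umi, alt_reads,
                    total_reads,
                )
            )
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)


def write_evidence(evidence, path) -> None:
    evidence_to_frame(evidence).to_csv(path, sep="\t", index=False)


def frame_to_evidence(df: pd.DataFrame) -> list:
    """Group a per-UMI table back into :class:`VariantEvidence` records."""
    out = []
    keys = ["cell_id", "donor_id", "chrom", "pos", "ref", "alt", "tlod",
            "exome_depth"]
    for key, grp in df.groupby(keys, sort=False):
        out.append(
            VariantEvidence(
                cell_id=str(key[0]), donor_id=str(key[1]), chrom=str(key[2]),
                pos=int(key[3]), ref=str(key[4]), alt=str(key[5]),
                tlod=float(key[6]), exome_depth=int(key[7]),
                umi_support=tuple(
                    (str(u), int(a), int(t))
                    for u, a, t in zip(
                        grp["umi"], grp["alt_reads"], grp["total_reads"]
                    )
                ),
            )
        )
    return out


def read_evidence(path) -> list:
    return frame_to_evidence(pd.read_csv(path, sep="\t"))


def read_vcf_evidence(path, cell_id: str, donor_id: str) -> list:
    """Ingest one cell's VCF into :class:`VariantEvidence` records.

    Expects INFO ``TLOD`` and ``EDP`` (exome depth) and per-UMI support in
    the FORMAT fields ``UMI`` (comma-joined barcodes), ``UALT`` and
    ``UTOT`` (comma-joined per-UMI alt/total read counts).  Multi-allelic
    rows contribute one record per alt.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            tlod = rec.info.get("TLOD")
            if isinstance(tlod, tuple):
                tlod = tlod[0]
            edp = rec.info.get("EDP", 0)
            sample = rec.samples[0]

            def _values(field):
                val = sample.get(field, "")
                if isinstance(val, (tuple, list)):
                    return [str(v) for v in val]
                return str(val).split(",")

            umis = _values("UMI")
            ualt = [int(x) for x in _values("UALT")]
            utot = [int(x) for x in _values("UTOT")]
            support = tuple(zip(umis, ualt, utot))
            for alt in rec.alts or ():
                out.append(
                    VariantEvidence(
                        cell_id=cell_id, donor_id=donor_id,
                        chrom=str(rec.chrom), pos=int(rec.pos),
                        ref=str(rec.ref), alt=str(alt),
                        tlod=float(tlod if tlod is not None else 0.0),
                        exome_depth=int(edp),
                        umi_support=support,
                    )
                )
    return out
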