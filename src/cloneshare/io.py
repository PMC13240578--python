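"""Repertoire and expression I/O.

Reads 10x-style ``filtered_contig_annotations.csv`` or AIRR Rearrangement TSV
files into :class:`ContigRecord` lists, cell metadata TSVs into
:class:`CellRecord` lists, and Matrix Market count matrices (with
features/barcodes sidecars) into :class:`ExpressionMatrix` objects.  Chains
are collapsed into subject-scoped clonotypes with
:func:`collapse_to_clonotypes`.

Clonotype identity is subject-scoped by construction: a clone id is always
prefixed with the subject id, so clones can never span two subjects (public
clones are out of scope here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, IntegrityError, ValidationError

logger = logging.getLogger("cloneshare")


class Chain(str, Enum):
    TRA = "TRA"
    TRB = "TRB"
    IGH = "IGH"
    IGK = "IGK"
    IGL = "IGL"


class Compartment(str, Enum):
    LUNG = "LUNG"
    BALF = "BALF"
    PBMC = "PBMC"


class Group(str, Enum):
    PNEUMONIA = "PNEUMONIA"
    CONTROL = "CONTROL"


class Dialect(str, Enum):
    TENX_CSV = "TENX_CSV"
    AIRR_TSV = "AIRR_TSV"


class ClonePolicy(str, Enum):
    """How a clonotype key is built from a barcode's productive chains.

    NT_VJ  -- sorted set of (chain, V, J, CDR3 nucleotide) tuples (vendor default)
    AA_VJ  -- same with the CDR3 amino-acid sequence
    RAW_ID -- the vendor clonotype id carried in the contig file
    """

    NT_VJ = "NT_VJ"
    AA_VJ = "AA_VJ"
    RAW_ID = "RAW_ID"


class ReceptorType(str, Enum):
    TCR = "TCR"
    BCR = "BCR"


TCR_CHAINS = {Chain.TRA, Chain.TRB}
BCR_CHAINS = {Chain.IGH, Chain.IGK, Chain.IGL}


@dataclass(frozen=True)
class ContigRecord:
    """One receptor chain (contig) observed in one cell."""

    barcode: str
    chain: Chain
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    productive: bool
    umis: int
    c_gene: str = ""
    raw_clonotype_id: str = ""

    def __post_init__(self) -> None:
        if self.umis < 0:
            raise ValidationError(f"umis must be >= 0 (barcode {self.barcode})")
        if self.productive and not self.cdr3_nt:
            raise ValidationError(
                f"productive contig with empty cdr3_nt (barcode {self.barcode})"
            )


@dataclass(frozen=True)
class CellRecord:
    """One cell with its sample annotations and QC covariates."""

    barcode: str
    subject_id: str
    compartment: Compartment
    group: Group
    cluster: str
    mito_fraction: Optional[float] = None
    n_genes: Optional[int] = None


@dataclass(frozen=True)
class CloneAssignment:
    """A barcode's clonotype membership, scoped to its subject."""

    barcode: str
    subject_id: str
    clone_id: str
    receptor_type: ReceptorType
    isotype: Optional[str] = None


@dataclass
class ExpressionMatrix:
    """Sparse gene-by-cell count matrix with an optional normalized layer."""

    genes: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix
    normalized: Optional[sp.csr_matrix] = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, symbols: Sequence[str]) -> list[int]:
        lookup = {g: i for i, g in enumerate(self.genes)}
        return [lookup[s] for s in symbols if s in lookup]

    def to_anndata(self):
        """Convert to an AnnData (cells x genes), if anndata is installed."""
        import anndata

        ad = anndata.AnnData(X=self.counts.T.tocsr())
        ad.obs_names = list(self.barcodes)
        ad.var_names = list(self.genes)
        if self.normalized is not None:
            ad.layers["lognorm"] = self.normalized.T.tocsr()
        return ad


# ---------------------------------------------------------------------------
# contig tables

_TENX_COLUMNS = [
    "barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt",
    "productive", "umis", "c_gene", "raw_clonotype_id",
]
_AIRR_COLUMNS = [
    "cell_id", "locus", "v_call", "j_call", "junction", "junction_aa",
    "productive", "consensus_count", "c_call",
]

_TRUE_TOKENS = {"true", "t"}


def _parse_bool(token: str) -> bool:
    return token.strip().lower() in _TRUE_TOKENS


def _read_table(path, sep: str, mandatory: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: header only, no data rows")
    return df


def read_contig_table(path, dialect: Dialect = Dialect.TENX_CSV) -> list[ContigRecord]:
    """Read receptor contigs from a 10x CSV or an AIRR Rearrangement TSV."""
    dialect = Dialect(dialect)
    if dialect is Dialect.TENX_CSV:
        df = _read_table(path, ",", _TENX_COLUMNS)
        records = [
            ContigRecord(
                barcode=row.barcode,
                chain=Chain(row.chain),
                v_gene=row.v_gene,
                j_gene=row.j_gene,
                cdr3_nt=row.cdr3_nt,
                cdr3_aa=row.cdr3,
                productive=_parse_bool(row.productive),
                umis=int(row.umis),
                c_gene=row.c_gene,
                raw_clonotype_id=row.raw_clonotype_id,
            )
            for row in df.itertuples(index=False)
        ]
    else:
        df = _read_table(path, "\t", _AIRR_COLUMNS)
        records = [
            ContigRecord(
                barcode=row.cell_id,
                chain=Chain(row.locus),
                v_gene=row.v_call,
                j_gene=row.j_call,
                cdr3_nt=row.junction,
                cdr3_aa=row.junction_aa,
                productive=_parse_bool(row.productive),
                umis=int(row.consensus_count),
                c_gene=row.c_call,
            )
            for row in df.itertuples(index=False)
        ]
    return records


def write_contig_table(records: Sequence[ContigRecord], path,
                       dialect: Dialect = Dialect.TENX_CSV) -> None:
    dialect = Dialect(dialect)
    if dialect is Dialect.TENX_CSV:
        df = pd.DataFrame(
            {
                "barcode": [r.barcode for r in records],
                "chain": [r.chain.value for r in records],
                "v_gene": [r.v_gene for r in records],
                "j_gene": [r.j_gene for r in records],
                "cdr3": [r.cdr3_aa for r in records],
                "cdr3_nt": [r.cdr3_nt for r in records],
                "productive": ["True" if r.productive else "False" for r in records],
                "umis": [r.umis for r in records],
                "c_gene": [r.c_gene for r in records],
                "raw_clonotype_id": [r.raw_clonotype_id for r in records],
            }
        )
        df.to_csv(path, index=False)
    else:
        df = pd.DataFrame(
            {
                "cell_id": [r.barcode for r in records],
                "locus": [r.chain.value for r in records],
                "v_call": [r.v_gene for r in records],
                "j_call": [r.j_gene for r in records],
                "junction": [r.cdr3_nt for r in records],
                "junction_aa": [r.cdr3_aa for r in records],
                "productive": ["T" if r.productive else "F" for r in records],
                "consensus_count": [r.umis for r in records],
                "c_call": [r.c_gene for r in records],
            }
        )
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cell metadata

_CELL_COLUMNS = [
    "barcode", "subject_id", "compartment", "group", "cluster",
    "mito_fraction", "n_genes",
]


def read_cell_metadata(path) -> list[CellRecord]:
    """Read the per-cell metadata TSV (barcode, subject, compartment, ...)."""
    df = _read_table(path, "\t", _CELL_COLUMNS)
    if df.duplicated(subset=["subject_id", "barcode"]).any():
        dupes = df[df.duplicated(subset=["subject_id", "barcode"])]["barcode"].tolist()
        raise IntegrityError(f"duplicate (subject_id, barcode) pairs: {dupes[:5]}")
    records = []
    for row in df.itertuples(index=False):
        if not row.compartment or not row.group:
            raise ValidationError(
                f"barcode {row.barcode}: compartment and group must be non-missing"
            )
        records.append(
            CellRecord(
                barcode=row.barcode,
                subject_id=row.subject_id,
                compartment=Compartment(row.compartment),
                group=Group(row.group),
                cluster=row.cluster,
                mito_fraction=float(row.mito_fraction) if row.mito_fraction else None,
                n_genes=int(row.n_genes) if row.n_genes else None,
            )
        )
    return records


def write_cell_metadata(cells: Sequence[CellRecord], path) -> None:
    df = pd.DataFrame(
        {
            "barcode": [c.barcode for c in cells],
            "subject_id": [c.subject_id for c in cells],
            "compartment": [c.compartment.value for c in cells],
            "group": [c.group.value for c in cells],
            "cluster": [c.cluster for c in cells],
            "mito_fraction": [
                "" if c.mito_fraction is None else repr(float(c.mito_fraction))
                for c in cells
            ],
            "n_genes": ["" if c.n_genes is None else c.n_genes for c in cells],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clonotype collapse

def _chain_key(contig: ContigRecord, policy: ClonePolicy) -> tuple:
    cdr3 = contig.cdr3_nt if policy is ClonePolicy.NT_VJ else contig.cdr3_aa
    return (contig.chain.value, contig.v_gene, contig.j_gene, cdr3)


def collapse_to_clonotypes(
    contigs: Sequence[ContigRecord],
    cells: Sequence[CellRecord],
    policy: ClonePolicy = ClonePolicy.NT_VJ,
) -> list[CloneAssignment]:
    """Collapse productive chains into subject-scoped clonotype assignments.

    Per barcode the clone key is built from productive chains only, keeping
    the two highest-UMI chains per locus (standard doublet-chain handling).
    Barcodes with no productive chain get no assignment; contig barcodes
    absent from ``cells`` are dropped (count logged).  Barcodes carrying both
    TCR and BCR chains are dropped as presumptive doublets (count logged).
    """
    policy = ClonePolicy(policy)
    barcode_subject: dict[str, str] = {}
    for cell in cells:
        prev = barcode_subject.get(cell.barcode)
        if prev is not None and prev != cell.subject_id:
            raise IntegrityError(
                f"barcode {cell.barcode} mapped to two subjects ({prev}, {cell.subject_id})"
            )
        barcode_subject[cell.barcode] = cell.subject_id

    by_barcode: dict[str, list[ContigRecord]] = {}
    n_dropped = 0
    for contig in contigs:
        if contig.barcode not in barcode_subject:
            n_dropped += 1
            continue
        by_barcode.setdefault(contig.barcode, []).append(contig)
    if n_dropped:
        logger.info("collapse_to_clonotypes: dropped %d contigs with unknown barcodes", n_dropped)

    assignments: list[CloneAssignment] = []
    n_mixed = 0
    for barcode in sorted(by_barcode):
        subject = barcode_subject[barcode]
        productive = [c for c in by_barcode[barcode] if c.productive]
        if not productive:
            continue
        # keep the two highest-UMI chains per locus
        kept: list[ContigRecord] = []
        for chain in Chain:
            locus = [c for c in productive if c.chain is chain]
            locus.sort(key=lambda c: (-c.umis, c.cdr3_nt, c.v_gene, c.j_gene))
            kept.extend(locus[:2])
        chains = {c.chain for c in kept}
        if chains & TCR_CHAINS and chains & BCR_CHAINS:
            n_mixed += 1
            continue
        receptor = ReceptorType.TCR if chains & TCR_CHAINS else ReceptorType.BCR

        if policy is ClonePolicy.RAW_ID:
            raw_ids = {c.raw_clonotype_id for c in kept if c.raw_clonotype_id}
            if not raw_ids:
                raise ValidationError(
                    f"policy RAW_ID but barcode {barcode} carries no raw_clonotype_id"
                )
            key = sorted(raw_ids)[0]
        else:
            key = ";".join(":".join(t) for t in sorted(_chain_key(c, policy) for c in kept))

        isotype = None
        if receptor is ReceptorType.BCR:
            heavies = sorted(
                (c for c in kept if c.chain is Chain.IGH),
                key=lambda c: (-c.umis, c.cdr3_nt),
            )
            if heavies and heavies[0].c_gene:
                isotype = heavies[0].c_gene

        assignments.append(
            CloneAssignment(
                barcode=barcode,
                subject_id=subject,
                clone_id=f"{subject}|{key}",
                receptor_type=receptor,
                isotype=isotype,
            )
        )
    if n_mixed:
        logger.info("collapse_to_clonotypes: dropped %d barcodes with mixed TCR/BCR chains", n_mixed)
    return assignments


def write_clone_assignments(assignments: Sequence[CloneAssignment], path) -> None:
    df = pd.DataFrame(
        {
            "barcode": [a.barcode for a in assignments],
            "subject_id": [a.subject_id for a in assignments],
            "clone_id": [a.clone_id for a in assignments],
            "receptor_type": [a.receptor_type.value for a in assignments],
            "isotype": [a.isotype or "" for a in assignments],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_matrix(mtx_path, features_path, barcodes_path) -> ExpressionMatrix:
    """Read a Matrix Market counts file with features/barcodes sidecars.

    Duplicate gene symbols are disambiguated deterministically with ".1",
    ".2", ... suffixes in file order.
    """
    for p in (mtx_path, features_path, barcodes_path):
        if not Path(p).exists():
            raise FormatError(f"file not found: {p}")
    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str,
                           keep_default_na=False)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str,
                           keep_default_na=False)
    # 10x features files carry (id, symbol, type); one-column sidecars carry symbols
    symbols = features.iloc[:, 1] if features.shape[1] >= 2 else features.iloc[:, 0]
    genes = list(symbols)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"MTX declares {mat.shape} but sidecars have "
            f"{len(genes)} features x {len(barcodes)} barcodes"
        )
    seen: dict[str, int] = {}
    unique = []
    for g in genes:
        if g in seen:
            seen[g] += 1
            unique.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            unique.append(g)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("counts matrix must contain integers")
    return ExpressionMatrix(genes=unique, barcodes=list(barcodes.iloc[:, 0]),
                            counts=mat.astype(np.int64))


def write_expression_matrix(expr: ExpressionMatrix, mtx_path, features_path,
                            barcodes_path) -> None:
    scipy.io.mmwrite(str(mtx_path), expr.counts.tocoo(), field="integer")
    pd.Series(expr.genes).to_csv(features_path, sep="\t", header=False, index=False)
    pd.Series(expr.barcodes).to_csv(barcodes_path, sep="\t", header=False, index=False)
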