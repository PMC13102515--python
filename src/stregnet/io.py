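"""Readers and writers for the on-disk formats the pipeline touches.

The spot x gene count matrix follows the 10x triplet convention: a Matrix
Market file plus ``barcodes.tsv`` and ``features.tsv``.  Spot positions are
a CSV in the style of Visium ``tissue_positions`` (barcode, in_tissue,
x, y with integer array coordinates).  Promoters are plain FASTA, motifs
are MEME-minimal text, and the gene annotation is a TSV with semicolon-
separated pathway tags and enrichment-term ids.

All readers validate and reject structurally inconsistent input rather
than repairing it, with two documented tolerances: position rows for
unknown barcodes are ignored with a warning, and an empty promoter FASTA
yields an empty set with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import BASES, PWM, MotifLibrary

logger = logging.getLogger(__name__)

MTX_FILE = "matrix.mtx"
BARCODES_FILE = "barcodes.tsv"
FEATURES_FILE = "features.tsv"

__all__ = [
    "CountMatrix",
    "SpotGeometry",
    "GeneAnnotation",
    "PromoterSet",
    "FormatError",
    "read_count_matrix",
    "write_count_matrix",
    "read_spot_positions",
    "write_spot_positions",
    "read_promoters",
    "write_promoters",
    "read_motifs",
    "write_motifs",
    "read_annotation",
    "write_annotation",
]


class FormatError(ValueError):
    """Structural inconsistency in an input file."""


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI count matrix, spots x genes.

    Counts are deduplicated molecule counts: one row per spot barcode, one
    column per gene, duplicate identifiers on either axis are invalid.
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        counts = sp.csr_matrix(self.counts)
        if counts.shape != (len(self.barcodes), len(self.gene_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.gene_ids)} genes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        data = counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise FormatError("counts must be non-negative integers")
        self.counts = counts.astype(np.int64)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset(
        self, spot_mask: np.ndarray | None = None, gene_mask: np.ndarray | None = None
    ) -> "CountMatrix":
        counts, barcodes, gene_ids = self.counts, self.barcodes, self.gene_ids
        if spot_mask is not None:
            counts = counts[spot_mask]
            barcodes = [b for b, keep in zip(barcodes, spot_mask) if keep]
        if gene_mask is not None:
            counts = counts[:, gene_mask]
            gene_ids = [g for g, keep in zip(gene_ids, gene_mask) if keep]
        return CountMatrix(counts, barcodes, gene_ids)


@dataclass
class SpotGeometry:
    """Array coordinates of spot barcodes on the capture grid.

    Coordinates are integer grid units; physical spot size (tens of
    microns on commercial slides) is metadata and never enters any
    computation here.
    """

    table: pd.DataFrame  # index barcode; columns x, y, in_tissue

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != ["x", "y", "in_tissue"]:
            t = t[["x", "y", "in_tissue"]]
        if t.index.has_duplicates:
            raise FormatError("duplicate barcodes in spot geometry")
        if t.duplicated(subset=["x", "y"]).any():
            dup = t[t.duplicated(subset=["x", "y"], keep=False)]
            raise FormatError(f"duplicate spot coordinates:\n{dup}")
        self.table = t.assign(
            x=t["x"].astype(int), y=t["y"].astype(int), in_tissue=t["in_tissue"].astype(bool)
        )

    def coords(self, barcodes: list[str]) -> np.ndarray:
        return self.table.loc[barcodes, ["x", "y"]].to_numpy()


@dataclass
class GeneAnnotation:
    """Per-gene metadata: symbol, TF status/family, pathway and term tags."""

    table: pd.DataFrame  # index gene_id; symbol, is_tf, tf_family, pathway_tags, term_ids

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise FormatError("duplicate gene ids in annotation")
        bad = t[t["is_tf"] & (t["tf_family"].fillna("") == "")]
        if len(bad):
            raise FormatError(f"TF genes without family: {list(bad.index)}")
        t = t.assign(
            pathway_tags=t["pathway_tags"].apply(_as_tag_set),
            term_ids=t["term_ids"].apply(_as_tag_set),
        )
        self.table = t

    @property
    def tf_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_tf"]])

    def family_of(self, gene_id: str) -> str:
        return str(self.table.at[gene_id, "tf_family"])

    def pathway_sets(self) -> dict[str, set[str]]:
        sets: dict[str, set[str]] = {}
        for gene_id, tags in self.table["pathway_tags"].items():
            for tag in tags:
                sets.setdefault(tag, set()).add(gene_id)
        return sets

    def term_sets(self) -> dict[str, set[str]]:
        sets: dict[str, set[str]] = {}
        for gene_id, terms in self.table["term_ids"].items():
            for term in terms:
                sets.setdefault(term, set()).add(gene_id)
        return sets

    def subset(self, gene_ids: list[str]) -> "GeneAnnotation":
        return GeneAnnotation(self.table.loc[gene_ids].copy())


def _as_tag_set(value) -> frozenset[str]:
    if isinstance(value, (set, frozenset, list, tuple)):
        return frozenset(str(v) for v in value if str(v))
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    return frozenset(v for v in str(value).split(";") if v)


@dataclass
class PromoterSet:
    """Uppercase promoter sequences over {A,C,G,T,N}, one per gene."""

    sequences: dict[str, str] = field(default_factory=dict)

    _ALPHABET = frozenset("ACGTN")

    def __post_init__(self) -> None:
        for gene_id, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - self._ALPHABET
            if bad:
                raise FormatError(
                    f"promoter {gene_id}: illegal character(s) {sorted(bad)}"
                )
            if len(seq) < 1:
                raise FormatError(f"promoter {gene_id}: empty sequence")
            self.sequences[gene_id] = seq

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sequences

    def __iter__(self):
        return iter(self.sequences)


# ---------------------------------------------------------------------------
# count matrix triplet


def read_count_matrix(directory: str | Path) -> CountMatrix:
    """Read a 10x-style MTX + barcodes + features triplet.

    On-disk orientation may be either genes x spots (the 10x convention)
    or spots x genes; it is inferred from which axis lengths match the
    barcode and feature lists, preferring the 10x convention when the
    matrix is square.
    """
    directory = Path(directory)
    barcodes = _read_id_list(directory / BARCODES_FILE)
    features = _read_id_list(directory / FEATURES_FILE)
    try:
        mat = scipy.io.mmread(directory / MTX_FILE)
    except ValueError as exc:
        raise FormatError(f"malformed matrix file: {exc}") from exc
    mat = sp.coo_matrix(mat)
    n_b, n_f = len(barcodes), len(features)
    if mat.shape == (n_f, n_b):
        mat = mat.T
    elif mat.shape != (n_b, n_f):
        raise FormatError(
            f"matrix shape {mat.shape} matches neither genes x spots "
            f"({n_f} x {n_b}) nor spots x genes ({n_b} x {n_f})"
        )
    if mat.data.size and not np.issubdtype(mat.dtype, np.integer):
        if np.any(mat.data != np.round(mat.data)):
            raise FormatError("non-integer entries in count matrix")
    if mat.data.size and np.any(mat.data < 0):
        raise FormatError("negative entries in count matrix")
    return CountMatrix(sp.csr_matrix(mat), barcodes, features)


def write_count_matrix(matrix: CountMatrix, directory: str | Path) -> None:
    """Write the triplet in the 10x convention (features x barcodes MTX)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        directory / MTX_FILE, sp.coo_matrix(matrix.counts.T), field="integer"
    )
    (directory / BARCODES_FILE).write_text(
        "".join(f"{b}\n" for b in matrix.barcodes)
    )
    (directory / FEATURES_FILE).write_text(
        "".join(f"{g}\n" for g in matrix.gene_ids)
    )


def _read_id_list(path: Path) -> list[str]:
    ids = [line.split("\t")[0].strip() for line in path.read_text().splitlines()]
    return [i for i in ids if i]


# ---------------------------------------------------------------------------
# spot positions


def read_spot_positions(csv_path: str | Path, barcodes: list[str]) -> SpotGeometry:
    """Read the positions CSV, restricted to the given barcodes.

    Rows for barcodes absent from the count matrix are ignored with a
    warning (slides carry more spots than tissue covers); a matrix barcode
    missing from the CSV is an error.
    """
    df = pd.read_csv(csv_path)
    required = {"barcode", "in_tissue", "x", "y"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FormatError(f"positions CSV missing columns: {sorted(missing_cols)}")
    if df["barcode"].duplicated().any():
        raise FormatError("duplicate barcodes in positions CSV")
    known = set(barcodes)
    extra = [b for b in df["barcode"] if b not in known]
    if extra:
        logger.warning(
            "ignoring %d position rows for barcodes not in the matrix", len(extra)
        )
    df = df[df["barcode"].isin(known)].set_index("barcode")
    missing = [b for b in barcodes if b not in df.index]
    if missing:
        raise FormatError(f"no position for barcode(s): {missing[:5]}")
    return SpotGeometry(df.loc[barcodes, ["x", "y", "in_tissue"]])


def write_spot_positions(geometry: SpotGeometry, csv_path: str | Path) -> None:
    out = geometry.table.reset_index(names="barcode")
    out[["barcode", "in_tissue", "x", "y"]].to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# promoters (FASTA)


def read_promoters(fasta_path: str | Path) -> PromoterSet:
    """Read one promoter per gene from FASTA; header token = gene id."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate gene id in FASTA: {record.id}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        logger.warning("promoter FASTA %s contains no records", fasta_path)
    return PromoterSet(sequences)


def write_promoters(promoters: PromoterSet, fasta_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="")
        for gene_id, seq in sorted(promoters.sequences.items())
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# motifs (MEME minimal)
#
# The MEME-minimal dialect used here is the alphabet line plus, per motif,
# a MOTIF line and a letter-probability matrix.  A focused reader is used
# so that raw row sums can be validated to 1e-4 before renormalization
# (general-purpose parsers renormalize silently and require sections this
# dialect treats as optional).

_ROW_SUM_TOL = 1e-4


def read_motifs(meme_path: str | Path) -> MotifLibrary:
    lines = Path(meme_path).read_text().splitlines()
    motifs: dict[str, PWM] = {}
    i = 0
    saw_alphabet = False
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            if "ACGT" not in line.replace("=", " "):
                raise FormatError(f"unsupported alphabet line: {line!r}")
            saw_alphabet = True
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError("MOTIF line without a name")
            name = parts[1]
            i += 1
            # skip to the letter-probability header
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"motif {name!r} has no probability matrix")
                i += 1
            if i >= len(lines):
                raise FormatError(f"motif {name!r} has no probability matrix")
            i += 1
            rows = []
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or not _is_number_row(stripped):
                    break
                rows.append([float(v) for v in stripped.split()])
                i += 1
            if not rows:
                raise FormatError(f"motif {name!r} has width 0")
            mat = np.asarray(rows, dtype=float)
            if mat.shape[1] != 4:
                raise FormatError(f"motif {name!r}: expected 4 columns per row")
            row_sums = mat.sum(axis=1)
            off = np.abs(row_sums - 1.0)
            if np.any(off > _ROW_SUM_TOL):
                j = int(np.argmax(off))
                raise FormatError(
                    f"motif {name!r}: row {j} sums to {row_sums[j]:.6g}, not 1"
                )
            mat = mat / row_sums[:, None]  # renormalize within tolerance
            if name in motifs:
                raise FormatError(f"duplicate motif name {name!r}")
            motifs[name] = PWM(name, mat.T)
            continue
        i += 1
    if not saw_alphabet:
        logger.warning("motif file %s has no ALPHABET line; assuming ACGT", meme_path)
    return MotifLibrary(motifs)


def _is_number_row(line: str) -> bool:
    try:
        [float(v) for v in line.split()]
        return True
    except ValueError:
        return False


def write_motifs(library: MotifLibrary, meme_path: str | Path) -> None:
    out = ["MEME version 4", "", "ALPHABET= ACGT", ""]
    for name in library.families:
        pwm = library[name]
        out.append(f"MOTIF {name}")
        out.append(
            f"letter-probability matrix: alphabet= 4 w= {pwm.width} nsites= 20 E= 0"
        )
        for col in pwm.probs.T:
            out.append(" ".join(f"{v:.6f}" for v in col))
        out.append("")
    Path(meme_path).write_text("\n".join(out))


# ---------------------------------------------------------------------------
# gene annotation TSV

_ANNOT_COLS = ["gene_id", "symbol", "is_tf", "tf_family", "pathway_tags", "term_ids"]


def read_annotation(tsv_path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    df = df.set_index("gene_id")
    df["is_tf"] = df["is_tf"].str.lower().map({"true": True, "false": False, "1": True, "0": False})
    if df["is_tf"].isna().any():
        raise FormatError("is_tf column must be true/false")
    return GeneAnnotation(df[["symbol", "is_tf", "tf_family", "pathway_tags", "term_ids"]])


def write_annotation(annotation: GeneAnnotation, tsv_path: str | Path) -> None:
    t = annotation.table.copy()
    t["pathway_tags"] = t["pathway_tags"].apply(lambda s: ";".join(sorted(s)))
    t["term_ids"] = t["term_ids"].apply(lambda s: ";".join(sorted(s)))
    t["is_tf"] = t["is_tf"].map({True: "true", False: "false"})
    t.reset_index(names="gene_id")[_ANNOT_COLS].to_csv(tsv_path, sep="\t", index=False)
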