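"""Reading annotated genomes and writing pipeline outputs.

Genomes enter the pipeline as proteomes: one :class:`ProteinRecord` per
annotated protein, carrying the free-text product annotation that keyword
screening matches against.  Three input routes are supported and treated
equivalently downstream:

* protein FASTA (``>id product description`` headers),
* GenBank flat files (CDS features with ``translation`` qualifiers),
* GFF3 + genomic FASTA (CDS spans extracted and translated with the
  bacterial genetic code, table 11).

Coordinates are kept 1-based inclusive throughout (the GenBank/GFF3
convention).  Output writers cover the presence/absence matrix (TSV with a
sibling feature→category map) and Newick trees for gene-content dendrograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ProteinRecord",
    "GenomeRecord",
    "GenomeParseError",
    "read_protein_fasta",
    "write_protein_fasta",
    "read_genbank",
    "read_gff3_with_fasta",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_newick",
    "newick_string",
]

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class GenomeParseError(ValueError):
    """Raised when a genome input file violates the documented contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One annotated protein of a genome.

    ``coords`` when present is ``(contig, start, end, strand)`` with 1-based
    inclusive positions, ``start <= end`` and strand ``"+"``/``"-"``.
    """

    protein_id: str
    genome_id: str
    product: str
    sequence: str
    coords: tuple[str, int, int, str] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeParseError(
                f"protein {self.protein_id!r}: empty sequence"
            )
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence, start=1) if c in bad
            )
            raise GenomeParseError(
                f"protein {self.protein_id!r}: illegal residue "
                f"{self.sequence[pos - 1]!r} at position {pos}"
            )
        if self.coords is not None:
            _, start, end, strand = self.coords
            if start > end or start < 1 or strand not in "+-":
                raise GenomeParseError(
                    f"protein {self.protein_id!r}: invalid coords {self.coords}"
                )


@dataclass(frozen=True)
class GenomeRecord:
    """One genome's proteome plus its display label and taxon group."""

    genome_id: str
    label: str
    taxon_group: str
    proteins: tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.proteins:
            if p.protein_id in seen:
                raise GenomeParseError(
                    f"genome {self.genome_id!r}: duplicate protein id "
                    f"{p.protein_id!r}"
                )
            seen.add(p.protein_id)

    def __len__(self) -> int:
        return len(self.proteins)


def _clean_protein_seq(seq: str) -> str:
    """Uppercase, strip terminal stop, map internal stops/ambiguity to X."""
    seq = seq.upper().rstrip("*")
    return "".join(c if c in VALID_RESIDUES else "X" for c in seq)


# ---------------------------------------------------------------------------
# protein FASTA


def read_protein_fasta(
    path: str | Path,
    genome_id: str | None = None,
    taxon_group: str = "unassigned",
    label: str | None = None,
) -> GenomeRecord:
    """Read a proteome from FASTA; header = ``id<space>product description``.

    ``genome_id`` defaults to the file stem.  Terminal ``*`` stop characters
    are stripped; duplicate ids and illegal residues raise
    :class:`GenomeParseError`.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        product = rec.description[len(rec.id):].strip() if rec.description else ""
        proteins.append(
            ProteinRecord(
                protein_id=rec.id,
                genome_id=gid,
                product=product,
                sequence=_clean_protein_seq(str(rec.seq)),
            )
        )
    if not proteins:
        raise GenomeParseError(f"{path}: no FASTA records")
    return GenomeRecord(
        genome_id=gid,
        label=label if label is not None else gid,
        taxon_group=taxon_group,
        proteins=tuple(proteins),
    )


def write_protein_fasta(genome: GenomeRecord, path: str | Path) -> None:
    """Write a proteome back to FASTA (inverse of :func:`read_protein_fasta`)."""
    with open(path, "w") as fh:
        for p in genome.proteins:
            header = f">{p.protein_id} {p.product}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# GenBank


def read_genbank(
    path: str | Path,
    taxon_group: str = "unassigned",
    genome_id: str | None = None,
) -> GenomeRecord:
    """Read CDS translations from a GenBank flat file.

    Protein ids come from the ``protein_id`` qualifier, falling back to
    ``locus_tag``; a CDS with neither is an error, as is a file without any
    translated CDS.  Feature locations become 1-based inclusive coords.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    label = gid
    proteins = []
    for rec in SeqIO.parse(str(path), "genbank"):
        if rec.annotations.get("organism") and label == gid:
            label = f"{gid}"
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            translation = quals.get("translation", [None])[0]
            if translation is None:
                continue
            pid = quals.get("protein_id", quals.get("locus_tag", [None]))[0]
            if pid is None:
                raise GenomeParseError(
                    f"{path}: CDS at {feat.location} lacks both protein_id "
                    "and locus_tag"
                )
            strand = "-" if feat.location.strand == -1 else "+"
            coords = (
                rec.id,
                int(feat.location.start) + 1,
                int(feat.location.end),
                strand,
            )
            proteins.append(
                ProteinRecord(
                    protein_id=pid,
                    genome_id=gid,
                    product=quals.get("product", [""])[0],
                    sequence=_clean_protein_seq(translation),
                    coords=coords,
                )
            )
    if not proteins:
        raise GenomeParseError(f"{path}: no CDS features with translations")
    return GenomeRecord(
        genome_id=gid, label=label, taxon_group=taxon_group,
        proteins=tuple(proteins),
    )


# ---------------------------------------------------------------------------
# GFF3 + genomic FASTA


def read_gff3_with_fasta(
    gff_path: str | Path,
    fasta_path: str | Path,
    taxon_group: str = "unassigned",
    genome_id: str | None = None,
) -> GenomeRecord:
    """Extract, splice and translate CDS features from GFF3 + genomic FASTA.

    Multi-segment CDS sharing one ``ID`` are concatenated in coordinate order
    and, on the ``-`` strand, reverse-complemented as a unit so translation
    runs 5'->3' on the coding strand.  Lengths not divisible by three are
    truncated with a logged warning; ambiguous codons translate to ``X``.
    """
    gff_path = Path(gff_path)
    gid = genome_id if genome_id is not None else gff_path.stem
    contigs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }

    # segments per CDS ID, in file order
    cds: dict[str, list[tuple[str, int, int, str]]] = {}
    products: dict[str, str] = {}
    order: list[str] = []
    for line in gff_path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9 or parts[2] != "CDS":
            continue
        contig, _, _, start, end, _, strand, _, attrs = parts
        attributes = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        cid = attributes.get("ID", f"cds{len(cds)}")
        if cid not in cds:
            cds[cid] = []
            order.append(cid)
            products[cid] = attributes.get("product", "")
        cds[cid].append((contig, int(start), int(end), strand))

    if not cds:
        raise GenomeParseError(f"{gff_path}: no CDS features")

    proteins = []
    for cid in order:
        segments = sorted(cds[cid], key=lambda s: (s[0], s[1]))
        nt = []
        for contig, start, end, strand in segments:
            if contig not in contigs:
                raise GenomeParseError(
                    f"{gff_path}: contig {contig!r} for CDS {cid!r} missing "
                    "from FASTA"
                )
            nt.append(contigs[contig][start - 1 : end])
        seq = "".join(nt)
        strand = segments[0][3]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        if len(seq) % 3:
            logger.warning(
                "CDS %s length %d not divisible by 3; truncating trailing bases",
                cid, len(seq),
            )
            seq = seq[: len(seq) - len(seq) % 3]
        aa = _clean_protein_seq(str(Seq(seq).translate(table=11)))
        coords = (
            segments[0][0],
            min(s[1] for s in segments),
            max(s[2] for s in segments),
            strand,
        )
        proteins.append(
            ProteinRecord(
                protein_id=cid,
                genome_id=gid,
                product=products[cid],
                sequence=aa,
                coords=coords,
            )
        )
    return GenomeRecord(
        genome_id=gid, label=gid, taxon_group=taxon_group,
        proteins=tuple(proteins),
    )


# ---------------------------------------------------------------------------
# matrix TSV

def write_matrix_tsv(matrix, path: str | Path) -> None:
    """Write a presence/absence matrix as TSV plus a feature→category map.

    The matrix TSV has header ``genome_id`` + feature ids and 0/1 cells in
    input genome order; the sibling ``<path stem>.features.tsv`` maps each
    feature id to its category id.
    """
    path = Path(path)
    df = pd.DataFrame(
        matrix.cells, index=matrix.genome_ids, columns=matrix.feature_ids
    )
    df.index.name = "genome_id"
    df.to_csv(path, sep="\t")
    fmap = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "category_id": [matrix.feature_category[f] for f in matrix.feature_ids],
        }
    )
    fmap.to_csv(path.with_suffix(".features.tsv"), sep="\t", index=False)


def read_matrix_tsv(path: str | Path, mode: str = "enzyme"):
    """Read back a matrix written by :func:`write_matrix_tsv`."""
    from .pangenome import PresenceMatrix  # local import avoids a cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="genome_id", dtype=str)
    df.index = df.index.astype(str)
    fmap_path = path.with_suffix(".features.tsv")
    if fmap_path.exists() and len(df.columns):
        fmap = pd.read_csv(fmap_path, sep="\t", dtype=str)
        feature_category = dict(zip(fmap["feature_id"], fmap["category_id"]))
    else:
        feature_category = {f: "uncategorized" for f in df.columns}
    return PresenceMatrix(
        genome_ids=tuple(df.index),
        feature_ids=tuple(df.columns),
        cells=df.to_numpy(dtype=int),
        feature_category=feature_category,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Newick

_NEWICK_RESERVED = set("(),:;'[] \t\n")


def _quote_label(label: str) -> str:
    if any(c in _NEWICK_RESERVED for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree) -> str:
    """Render a :class:`~anfscreen.clustering.ClusterTree` as Newick.

    Branch lengths are parent-child height differences; leaves sit at height
    zero, so patristic distances reproduce the ultrametric cophenetic
    distances.
    """

    def render(node, parent_height: float) -> str:
        if node.is_leaf:
            return f"{_quote_label(node.label)}:{parent_height - node.height:g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{parent_height - node.height:g}"

    root = tree.root
    if root.is_leaf:
        return f"{_quote_label(root.label)};"
    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner});"


def write_newick(tree, path: str | Path) -> None:
    """Write *tree* in Newick format with a terminating semicolon."""
    Path(path).write_text(newick_string(tree) + "\n")
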