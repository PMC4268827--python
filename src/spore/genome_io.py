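"""Genome, annotation and track I/O.

Reads genomes (FASTA) and gene annotations (GFF3 or a simple gene-table TSV)
into canonical in-memory structures, derives strand-classified intergenic
regions, and reads/writes fixedStep WIG tracks and TFBS tables.

Coordinate convention: 0-based, half-open ``[start, end)`` everywhere inside
the package. GFF3 (1-based inclusive) and WIG (1-based) are converted at the
boundary, so ``end - start`` is always a length in nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

FEATURE_CLASSES = {
    "orf_verified",
    "orf_uncharacterized",
    "transposon",
    "rRNA",
    "pseudogene",
    "cds",
}

#: default GFF feature types kept per annotation source
DEFAULT_FEATURE_FILTER = frozenset({"gene", "CDS", "cds", "pseudogene",
                                    "rRNA_gene", "transposable_element_gene"})


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class FormatError(ValueError):
    """Unparseable file; message names the offending line."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval. ``start < end``; the start codon lies at ``start`` on
    the + strand and at ``end`` on the − strand."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str = "cds"

    def __post_init__(self):
        if self.start >= self.end:
            raise AnnotationError(
                f"gene {self.id}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise AnnotationError(
                f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start_codon(self) -> int:
        """Genomic coordinate of the translation start (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def stop_codon(self) -> int:
        """Genomic coordinate of the translation stop (strand-aware)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class GeneSet:
    """Ordered, strand-aware gene intervals grouped by chromosome."""

    records: list[GeneRecord]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda g: (g.chrom, g.start, g.end))

    def __len__(self) -> int:
        return len(self.records)

    def by_chrom(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for g in self.records:
            out.setdefault(g.chrom, []).append(g)
        return out

    def chroms(self) -> list[str]:
        seen = dict.fromkeys(g.chrom for g in self.records)
        for c in self.chrom_lengths:
            seen.setdefault(c)
        return list(seen)

    def validate(self) -> None:
        """Raise :class:`AnnotationError` on out-of-bounds or unsorted records."""
        prev: GeneRecord | None = None
        for g in self.records:
            if self.chrom_lengths:
                if g.chrom not in self.chrom_lengths:
                    raise AnnotationError(
                        f"gene {g.id}: chromosome {g.chrom} has no declared length")
                if g.end > self.chrom_lengths[g.chrom]:
                    raise AnnotationError(
                        f"gene {g.id}: end {g.end} beyond chromosome "
                        f"{g.chrom} length {self.chrom_lengths[g.chrom]}")
            if prev is not None and prev.chrom == g.chrom and prev.start > g.start:
                raise AnnotationError("records not sorted by start")
            prev = g


# intergenic region classes, fixed by the flanking strand pair
CONVERGENT = "convergent"
DIVERGENT = "divergent"
TANDEM = "tandem"
BORDER = "border"

_CLASS_BY_STRANDS = {
    ("+", "-"): CONVERGENT,
    ("-", "+"): DIVERGENT,
    ("+", "+"): TANDEM,
    ("-", "-"): TANDEM,
}


@dataclass(frozen=True)
class IntergenicRegion:
    """Gap between adjacent genes; ``region_class`` follows the strand rule
    (+,−)→convergent, (−,+)→divergent, co-directional→tandem, one flank
    missing→border."""

    chrom: str
    start: int
    end: int
    region_class: str
    left_gene: GeneRecord | None = None
    right_gene: GeneRecord | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_region(left_strand: str | None, right_strand: str | None) -> str:
    if left_strand is None or right_strand is None:
        return BORDER
    return _CLASS_BY_STRANDS[(left_strand, right_strand)]


def derive_intergenic_regions(genes: GeneSet) -> list[IntergenicRegion]:
    """One region between each pair of adjacent genes plus a border region at
    each chromosome end. Overlapping adjacent genes yield a zero-length
    region anchored at the right gene's start."""
    regions: list[IntergenicRegion] = []
    for chrom, recs in genes.by_chrom().items():
        clen = genes.chrom_lengths.get(chrom)
        first = recs[0]
        regions.append(IntergenicRegion(
            chrom, 0, max(0, first.start), BORDER, None, first))
        for left, right in zip(recs, recs[1:]):
            start, end = left.end, right.start
            if end < start:  # overlap: clamp to a zero-length gap
                start = end
            regions.append(IntergenicRegion(
                chrom, start, end,
                classify_region(left.strand, right.strand), left, right))
        last_end = max(g.end for g in recs)
        if clen is None:
            clen = last_end
        regions.append(IntergenicRegion(
            chrom, min(last_end, clen), clen, BORDER, recs[-1], None))
    return regions


def upstream_region_of(gene: GeneRecord,
                       regions: Sequence[IntergenicRegion]) -> IntergenicRegion | None:
    """The intergenic region immediately upstream of a gene's start codon."""
    for r in regions:
        if r.chrom != gene.chrom:
            continue
        if gene.strand == "+" and r.right_gene is gene:
            return r
        if gene.strand == "-" and r.left_gene is gene:
            return r
    return None


def intergenic_lengths(regions: Iterable[IntergenicRegion],
                       include_border: bool = False) -> np.ndarray:
    """Lengths of intergenic regions; telomeric border gaps excluded by default."""
    return np.array([r.length for r in regions
                     if include_border or r.region_class != BORDER], dtype=float)


# ---------------------------------------------------------------------------
# annotation readers

def _read_gene_table(path: str, feature_filter: set[str]) -> list[GeneRecord]:
    """TSV dialect: chrom, start, end, strand, id, class (0-based half-open);
    header line optional (detected by non-numeric start)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 tab-separated "
                                  f"columns, got {len(parts)}")
            chrom, start, end, strand, gid, fclass = parts[:6]
            if lineno == 1 and not start.lstrip("-").isdigit():
                continue  # header
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if fclass in feature_filter:
                records.append(GeneRecord(gid, chrom, s, e, strand, fclass))
    return records


def _read_gff3(path: str, feature_filter: set[str]) -> list[GeneRecord]:
    import gffutils

    try:
        db = gffutils.create_db(path, dbfn=":memory:",
                                merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc
    records = []
    for feat in db.all_features():
        if feat.featuretype not in feature_filter:
            continue
        gid = feat.attributes.get("ID", [feat.id])[0]
        if feat.strand not in "+-":
            raise AnnotationError(
                f"feature {gid}: strand-less features are not supported; "
                "assign a strand or drop the record")
        # GFF3 is 1-based inclusive
        records.append(GeneRecord(gid, feat.seqid, feat.start - 1, feat.end,
                                  feat.strand, feat.featuretype))
    return records


def read_annotation(path: str,
                    feature_filter: Iterable[str] = DEFAULT_FEATURE_FILTER,
                    chrom_lengths: Mapping[str, int] | None = None) -> GeneSet:
    """Read a GFF3 file or a gene-table TSV into a :class:`GeneSet`.

    Only records whose feature type is in ``feature_filter`` are kept.
    A declared ``chrom_lengths`` map enables bounds checking; an annotation
    chromosome absent from it raises :class:`AnnotationError`.
    """
    feature_filter = set(feature_filter)
    if not feature_filter:
        raise ValueError("feature_filter must be non-empty")
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff") or (head and len(head.split("\t")) >= 8):
        records = _read_gff3(path, feature_filter)
    else:
        records = _read_gene_table(path, feature_filter)
    gs = GeneSet(records, dict(chrom_lengths or {}))
    if chrom_lengths is not None:
        gs.validate()
    return gs


def merge_exon_records(genes: GeneSet) -> GeneSet:
    """Collapse multiple same-id intervals (exons/CDS parts) into one record
    spanning min(start)…max(end). Same id on two chromosomes or strands is an
    annotation error."""
    by_id: dict[str, list[GeneRecord]] = {}
    for g in genes.records:
        by_id.setdefault(g.id, []).append(g)
    merged = []
    for gid, parts in by_id.items():
        chroms = {p.chrom for p in parts}
        strands = {p.strand for p in parts}
        if len(chroms) > 1:
            raise AnnotationError(f"gene {gid} spans chromosomes {sorted(chroms)}")
        if len(strands) > 1:
            raise AnnotationError(f"gene {gid} appears on both strands")
        merged.append(replace(parts[0],
                              start=min(p.start for p in parts),
                              end=max(p.end for p in parts)))
    return GeneSet(merged, dict(genes.chrom_lengths))


# ---------------------------------------------------------------------------
# sequence and track I/O

def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into ``{chrom: uppercase sequence}``."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA header {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_wig(curves, path: str, precision: int = 6) -> None:
    """Write one or more curves as fixedStep WIG (1-based start positions)."""
    from .curves import DensityCurve

    if isinstance(curves, DensityCurve):
        curves = {curves.chrom: curves}
    with open(path, "w") as fh:
        first = next(iter(curves.values()))
        if first.label:
            fh.write(f'track type=wiggle_0 name="{first.label}"\n')
        for chrom, c in curves.items():
            steps = np.diff(c.positions())
            if len(steps) and not np.all(steps == c.step):
                raise FormatError("write_wig requires a uniform grid")
            fh.write(f"fixedStep chrom={chrom} start={c.start + 1} "
                     f"step={c.step} span={c.step}\n")
            for v in c.values:
                fh.write(f"{v:.{precision}g}\n")


def read_wig(path: str):
    """Read a fixedStep WIG file into ``{chrom: DensityCurve}``."""
    from .curves import DensityCurve

    out = {}
    chrom = None
    start = step = None
    values: list[float] = []
    label = ""

    def flush():
        if chrom is not None:
            out[chrom] = DensityCurve(chrom, start, step,
                                      np.array(values, dtype=float), label)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("track"):
                if 'name="' in line:
                    label = line.split('name="', 1)[1].split('"', 1)[0]
                continue
            if line.startswith("fixedStep"):
                flush()
                fields = dict(kv.split("=", 1) for kv in line.split()[1:])
                chrom = fields["chrom"]
                start = int(fields["start"]) - 1
                step = int(fields.get("step", 1))
                values = []
            elif line.startswith("variableStep"):
                raise FormatError(f"{path}:{lineno}: variableStep unsupported")
            else:
                try:
                    values.append(float(line))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad value {line!r}") from exc
    flush()
    return out


def read_tfbs(path: str,
              chrom_lengths: Mapping[str, int] | None = None) -> dict[str, list[int]]:
    """Read a TSV of (gene id, chrom, position) into ``{gene: [positions]}``,
    deduplicated and sorted. Positions are 0-based."""
    table: dict[str, set[int]] = {}
    chrom_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            gid, chrom, pos = parts[0], parts[1], int(parts[2])
            if chrom_lengths is not None and not (0 <= pos < chrom_lengths[chrom]):
                raise AnnotationError(
                    f"TFBS of gene {gid} at {pos} outside chromosome {chrom}")
            table.setdefault(gid, set()).add(pos)
            chrom_of[gid] = chrom
    return {g: sorted(ps) for g, ps in table.items()}


def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    """Read BED3+ intervals as (chrom, start, end, name); name '' if absent."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_bed(intervals: Iterable[tuple], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")
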