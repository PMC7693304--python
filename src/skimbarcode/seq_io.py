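"""Sequence, alignment, taxon-table and feature I/O.

All coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is converted on read.  Sequences are uppercased and ambiguity codes other
than N are mapped to N (p-distance treats them as missing either way).
Strand is recorded for features but locus extraction never
reverse-complements: every downstream statistic is strand-agnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

UNALIGNED_ALPHABET = frozenset("ACGTN")
ALIGNED_ALPHABET = frozenset("ACGTN-")
_AMBIGUITY = frozenset("RYSWKMBDHV")

# GFF3 type -> feature class.  Anything unlisted falls through to "other".
GFF3_CLASS_MAP = {
    "CDS": "CDS",
    "gene": "CDS",
    "exon": "CDS",
    "mRNA": "CDS",
    "intron": "intron",
    "rRNA": "rRNA",
    "ETS": "ETS",
    "ITS": "ITS",
    "intergenic": "intergenic",
    "intergenic_region": "intergenic",
}

FEATURE_CLASSES = ("CDS", "intron", "intergenic", "rRNA", "ETS", "ITS", "other")


class AlignmentShapeError(ValueError):
    """Raised when records of a putative alignment differ in length."""


def _normalize_seq(raw: str, *, aligned: bool) -> str:
    s = raw.upper().replace(".", "-").replace("~", "-")
    out = []
    for ch in s:
        if ch in _AMBIGUITY:
            out.append("N")
        else:
            out.append(ch)
    s = "".join(out)
    allowed = ALIGNED_ALPHABET if aligned else UNALIGNED_ALPHABET
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)} in sequence")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence (aligned rows may contain '-')."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def ungapped(self) -> str:
        return self.seq.replace("-", "")


class Alignment:
    """A multiple sequence alignment: ordered records of equal length.

    Columns consisting entirely of gaps are stripped at construction
    (and logged); the result is the substrate of every downstream stage.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if len(records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence id(s): {dup}")
        n_cols = len(records[0].seq)
        for r in records[1:]:
            if len(r.seq) != n_cols:
                raise AlignmentShapeError(
                    f"record {r.id!r} has length {len(r.seq)}, expected {n_cols}"
                )
        mat = np.frombuffer(
            "".join(r.seq for r in records).encode("ascii"), dtype="S1"
        ).reshape(len(records), n_cols)
        all_gap = (mat == b"-").all(axis=0)
        if all_gap.any():
            log.info("stripping %d all-gap column(s)", int(all_gap.sum()))
            mat = mat[:, ~all_gap]
            if mat.shape[1] == 0:
                raise ValueError("alignment is all gaps")
            records = [
                SequenceRecord(r.id, mat[i].tobytes().decode("ascii"))
                for i, r in enumerate(records)
            ]
        self.records: list[SequenceRecord] = records
        self._matrix = np.ascontiguousarray(mat)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_cols(self) -> int:
        return self._matrix.shape[1]

    @property
    def n_seqs(self) -> int:
        return self._matrix.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """(n_seqs, n_cols) byte matrix; do not mutate."""
        return self._matrix

    def row(self, seq_id: str) -> str:
        return self.records[self.ids.index(seq_id)].seq

    def slice_columns(self, start: int, end: int) -> "Alignment":
        if not (0 <= start < end <= self.n_cols):
            raise ValueError(f"bad column slice [{start}, {end})")
        return Alignment(
            [SequenceRecord(r.id, r.seq[start:end]) for r in self.records]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.records == other.records

    def __repr__(self) -> str:
        return f"Alignment({self.n_seqs} seqs x {self.n_cols} cols)"


@dataclass
class TaxonTable:
    """id -> (species, variety, population); variety/population may be ''."""

    rows: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # a variety name must nest under exactly one species
        seen: dict[str, str] = {}
        for sid, (sp, var, _pop) in self.rows.items():
            if not var:
                continue
            if var in seen and seen[var] != sp:
                raise ValueError(
                    f"variety {var!r} mapped to both species "
                    f"{seen[var]!r} and {sp!r}"
                )
            seen[var] = sp

    def species_of(self, seq_id: str) -> str:
        return self._get(seq_id)[0]

    def variety_of(self, seq_id: str) -> str:
        return self._get(seq_id)[1]

    def population_of(self, seq_id: str) -> str:
        return self._get(seq_id)[2]

    def _get(self, seq_id: str) -> tuple[str, str, str]:
        try:
            return self.rows[seq_id]
        except KeyError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def ids(self) -> list[str]:
        return list(self.rows)

    def groups(self, level: str, ids: Iterable[str] | None = None) -> dict[str, list[str]]:
        """Group ids at ``level`` in {'species','variety','population'}.

        At the variety level, individuals of single-variety species group by
        species; varieties group separately (the finest named lineage).
        """
        ids = list(ids) if ids is not None else self.ids()
        out: dict[str, list[str]] = {}
        for sid in ids:
            sp, var, pop = self._get(sid)
            if level == "species":
                key = sp
            elif level == "variety":
                key = f"{sp}|{var}" if var else sp
            elif level == "population":
                key = f"{sp}|{var}|{pop}"
            else:
                raise ValueError(f"unknown level {level!r}")
            out.setdefault(key, []).append(sid)
        return out

    def multi_variety_species(self) -> list[str]:
        by_sp: dict[str, set[str]] = {}
        for sp, var, _ in self.rows.values():
            if var:
                by_sp.setdefault(sp, set()).add(var)
        return sorted(sp for sp, vs in by_sp.items() if len(vs) >= 2)


@dataclass
class Feature:
    seq_id: str
    start: int  # 0-based half-open
    end: int
    name: str
    feature_class: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name!r}: bad interval [{self.start}, {self.end})"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")


@dataclass
class FeatureTable:
    features: list[Feature] = field(default_factory=list)

    def on(self, seq_id: str) -> list[Feature]:
        return [f for f in self.features if f.seq_id == seq_id]

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read unaligned sequences (gaps rejected)."""
    recs = _read_fasta_records(path, aligned=False)
    return recs


def _read_fasta_records(path: str | Path, *, aligned: bool) -> list[SequenceRecord]:
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _normalize_seq(str(rec.seq), aligned=aligned)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA; '.'/'~' are normalized to '-'.

    Raises :class:`AlignmentShapeError` naming the offending record if the
    rows differ in length.
    """
    return Alignment(_read_fasta_records(path, aligned=True))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


def write_alignment(aln: Alignment, path: str | Path) -> None:
    write_fasta(aln.records, path)


def read_taxon_table(path: str | Path) -> TaxonTable:
    """Read a TSV with header id/species/variety/population."""
    path = Path(path)
    rows: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["id", "species", "variety", "population"]
        idx = {}
        for col in required:
            if col not in header:
                raise ValueError(f"taxon table missing column {col!r}")
            idx[col] = header.index(col)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            sid = parts[idx["id"]].strip()
            if sid in rows:
                raise ValueError(f"duplicate id {sid!r} at line {lineno}")
            get = lambda c: parts[idx[c]].strip() if idx[c] < len(parts) else ""
            rows[sid] = (get("species"), get("variety"), get("population"))
    if not rows:
        raise ValueError(f"empty taxon table {path}")
    return TaxonTable(rows)


def write_taxon_table(table: TaxonTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tspecies\tvariety\tpopulation\n")
        for sid, (sp, var, pop) in table.rows.items():
            fh.write(f"{sid}\t{sp}\t{var}\t{pop}\n")


def _classify_gff3_type(gff_type: str) -> str:
    return GFF3_CLASS_MAP.get(gff_type, "other")


def read_features(path: str | Path) -> FeatureTable:
    """Read GFF3 (1-based inclusive) or BED (0-based half-open) by extension."""
    path = Path(path)
    ext = path.suffix.lower()
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if ext in (".gff", ".gff3"):
                if len(parts) < 8:
                    raise ValueError(f"{path}:{lineno}: malformed GFF3 line")
                seq_id, _src, gff_type = parts[0], parts[1], parts[2]
                start = int(parts[3]) - 1  # to 0-based half-open
                end = int(parts[4])
                strand = parts[6] if parts[6] in "+-" else "+"
                name = gff_type
                if len(parts) >= 9:
                    for kv in parts[8].split(";"):
                        if kv.startswith(("ID=", "Name=")):
                            name = kv.split("=", 1)[1]
                            break
                fclass = _classify_gff3_type(gff_type)
            elif ext == ".bed":
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed BED line")
                seq_id = parts[0]
                start, end = int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"feature{lineno}"
                strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
                fclass = _classify_gff3_type(name) if name in GFF3_CLASS_MAP else "other"
            else:
                raise ValueError(f"unrecognized feature file extension {ext!r}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start after conversion")
            feats.append(Feature(seq_id, start, end, name, fclass, strand))
    # overlaps are allowed but worth a note
    by_seq: dict[str, list[Feature]] = {}
    for f in feats:
        by_seq.setdefault(f.seq_id, []).append(f)
    for seq_id, fl in by_seq.items():
        fl = sorted(fl, key=lambda f: f.start)
        for a, b in zip(fl, fl[1:]):
            if b.start < a.end:
                log.info("overlapping features on %s: %s / %s", seq_id, a.name, b.name)
                break
    return FeatureTable(feats)


def write_features_gff3(table: FeatureTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in table.features:
            fh.write(
                f"{f.seq_id}\tskimbarcode\t{f.feature_class}\t{f.start + 1}\t{f.end}"
                f"\t.\t{f.strand}\t.\tName={f.name}\n"
            )


# ---------------------------------------------------------------------------
# locus extraction


def ungapped_to_column(aln: Alignment, ref_id: str) -> np.ndarray:
    """Column index of each ungapped position of ``ref_id``."""
    row = np.frombuffer(aln.row(ref_id).encode("ascii"), dtype="S1")
    return np.nonzero(row != b"-")[0]


def extract_locus(aln: Alignment, ref_id: str, start: int, end: int) -> Alignment:
    """Slice the alignment columns spanned by reference positions [start, end).

    Coordinates are on the ungapped reference sequence; the slice runs from
    the column holding reference base ``start`` up to (but excluding) the
    column holding base ``end``, so gaps interior to the locus are kept and
    adjacent loci tile the columns without loss or overlap.  Gap columns
    trailing the final reference base belong to the interval that ends there.
    """
    if ref_id not in aln.ids:
        raise KeyError(f"reference id {ref_id!r} not in alignment")
    cols = ungapped_to_column(aln, ref_id)
    if not (0 <= start < end <= len(cols)):
        raise ValueError(
            f"locus [{start}, {end}) exceeds ungapped length {len(cols)} of {ref_id!r}"
        )
    stop = int(cols[end]) if end < len(cols) else aln.n_cols
    return aln.slice_columns(int(cols[start]), stop)
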