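"""Hierarchical sequence simulator with known ground truth.

Emulates a genome-skimming barcoding design: two species, the second split
into two varieties, with multiple individuals sampled from a handful of
populations per lineage.  An ancestral sequence evolves along the fixed
hierarchy (species split -> variety split -> populations -> individuals);
substitutions are independent per-site single-hit events with probability
branch_divergence x window_multiplier and equal exchange among the three
alternative bases, so expectations stay analytic.  Lineage-specific indels
are planted on named branches and intra-molecule repeat pairs in the
ancestor.  The true alignment is emitted directly from the event history.

Defaults mirror the emulated study design: 16 + 10 + 6 individuals from
9 / 6 / 2 populations, 200-bp windows, and branch divergences on the scale
of the observed locus-wise distances (inter-species ~0.1, inter-variety
~0.01 substitutions/site).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .seq_io import (
    Alignment,
    Feature,
    FeatureTable,
    SequenceRecord,
    TaxonTable,
    write_alignment,
    write_fasta,
    write_features_gff3,
    write_taxon_table,
)
from .windows import window_partition

_BASE_CODES = np.frombuffer(b"ACGT", dtype="S1")

SPECIES_A = "sppA"
SPECIES_B = "sppB"
VARIETY_B1 = "var1"
VARIETY_B2 = "var2"

BRANCHES = ("speciesA", "speciesB", "varietyB1", "varietyB2")


def default_indel_plan() -> list[tuple[str, int, int]]:
    """(branch, length, count): ~75% of events <= 10 bp, two > 100 bp."""
    short_a = [1, 2, 2, 3, 3, 4, 5, 5, 6, 7, 8, 9, 10, 2, 4]
    plan = [("speciesA", l, 1) for l in short_a]
    plan += [("speciesA", 25, 1), ("speciesA", 40, 1), ("speciesA", 60, 1),
             ("speciesA", 150, 1)]
    plan += [("varietyB1", 4, 1), ("varietyB1", 7, 1), ("varietyB1", 120, 1)]
    return plan


def default_repeat_plan() -> list[tuple[int, float, str]]:
    # an exact ~300-bp inverted pair (trnQ-IR analog) and a diverged direct pair
    return [(300, 1.0, "inverted"), (200, 0.95, "direct")]


@dataclass
class SimConfig:
    n_individuals: tuple[int, int, int] = (16, 10, 6)  # sppA, var1, var2
    n_populations: tuple[int, int, int] = (9, 6, 2)
    seq_length: int = 12_000
    window_length: int = 200
    multipliers: list[float] | None = None  # per window; default Gamma draw
    multiplier_gamma_shape: float = 0.7
    d_s: float = 0.05   # species-branch divergence (subs/site)
    d_v: float = 0.005  # variety branch
    d_p: float = 0.001  # population branch
    d_i: float = 0.0005  # individual branch
    indel_plan: list[tuple[str, int, int]] = field(default_factory=default_indel_plan)
    repeat_plan: list[tuple[int, float, str]] = field(default_factory=default_repeat_plan)
    indel_margin: int = 25  # min ancestral spacing between planted events
    seed: int = 0

    def __post_init__(self) -> None:
        all_zero = self.d_s == self.d_v == self.d_p == self.d_i == 0
        if not all_zero and not (self.d_s > self.d_v > self.d_p >= self.d_i >= 0):
            raise ValueError("need d_s > d_v > d_p >= d_i >= 0 (or all zero)")
        if any(c < 1 for c in self.n_individuals):
            raise ValueError("each group needs >= 1 individual")
        if self.multipliers is not None and any(m <= 0 for m in self.multipliers):
            raise ValueError("multipliers must be > 0")


@dataclass
class PlantedIndel:
    branch: str
    kind: str  # 'insertion' | 'deletion'
    length: int
    anchor: int  # ancestral coordinate
    columns: tuple[int, int]  # global alignment columns, half-open
    expected_specificity: str


@dataclass
class PlantedRepeat:
    start1: int
    end1: int
    start2: int
    end2: int
    orientation: str
    identity: float


@dataclass
class TruthRecord:
    planted_indels: list[PlantedIndel]
    planted_repeats: list[PlantedRepeat]
    multipliers: list[float]
    windows: list[tuple[int, int]]
    groups: dict[str, dict[str, list[str]]]  # level -> group -> ids

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class SimResult:
    sequences: list[SequenceRecord]  # ungapped
    alignment: Alignment  # the true alignment
    taxa: TaxonTable
    features: FeatureTable
    truth: TruthRecord
    ancestor: str = ""  # the ancestral sequence carrying the planted repeats

    def write_bundle(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "sequences": outdir / "sequences.fasta",
            "alignment": outdir / "alignment.fasta",
            "taxa": outdir / "taxa.tsv",
            "features": outdir / "features.gff3",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.sequences, paths["sequences"])
        write_alignment(self.alignment, paths["alignment"])
        write_taxon_table(self.taxa, paths["taxa"])
        write_features_gff3(self.features, paths["features"])
        self.truth.to_json(paths["truth"])
        if self.ancestor:
            paths["ancestor"] = outdir / "ancestor.fasta"
            write_fasta([SequenceRecord("ancestor", self.ancestor)], paths["ancestor"])
        return paths


def _make_taxa(cfg: SimConfig) -> TaxonTable:
    rows: dict[str, tuple[str, str, str]] = {}
    specs = [
        (SPECIES_A, "", "A", cfg.n_individuals[0], cfg.n_populations[0]),
        (SPECIES_B, VARIETY_B1, "B1", cfg.n_individuals[1], cfg.n_populations[1]),
        (SPECIES_B, VARIETY_B2, "B2", cfg.n_individuals[2], cfg.n_populations[2]),
    ]
    for sp, var, prefix, n, npop in specs:
        for i in range(n):
            sid = f"{prefix}{i + 1:02d}"
            pop = f"{prefix}p{(i % npop) + 1}"  # round-robin
            rows[sid] = (sp, var, pop)
    return TaxonTable(rows)


def _plant_repeats(
    anc: np.ndarray, plan: list[tuple[int, float, str]], rng: np.random.Generator
) -> list[PlantedRepeat]:
    """Copy segments within the ancestor per the plan; returns coordinates."""
    from .repeats import revcomp

    L = len(anc)
    placed: list[tuple[int, int]] = []
    out = []
    for length, identity, orientation in plan:
        for _ in range(200):
            s1 = int(rng.integers(0, L - 2 * length - 10))
            s2 = int(rng.integers(s1 + length + 5, L - length))
            iv1, iv2 = (s1, s1 + length), (s2, s2 + length)
            if any(max(a[0], b[0]) < min(a[1], b[1]) for a in (iv1, iv2) for b in placed):
                continue
            seg = anc[s1 : s1 + length].copy()
            n_sub = int(round((1 - identity) * length))
            if n_sub:
                pos = rng.choice(length, size=n_sub, replace=False)
                seg[pos] = (seg[pos] + rng.integers(1, 4, size=n_sub)) % 4
            if orientation == "inverted":
                seg = 3 - seg[::-1]  # complement of codes 0..3 is 3-code
            anc[s2 : s2 + length] = seg
            placed.extend([iv1, iv2])
            out.append(PlantedRepeat(*iv1, *iv2, orientation, identity))
            break
        else:
            raise RuntimeError("could not place repeat without overlap")
    return out


_SPECIFICITY_OF_BRANCH = {
    "speciesA": "species-specific",
    "speciesB": "species-specific",
    "varietyB1": "variety-specific",
    "varietyB2": "variety-specific",
}


def _plan_indels(
    cfg: SimConfig, rng: np.random.Generator
) -> list[dict]:
    """Assign anchors/kinds to the planned indels, non-overlapping."""
    events = []
    for branch, length, count in cfg.indel_plan:
        for _ in range(count):
            events.append({"branch": branch, "length": int(length)})
    taken: list[tuple[int, int]] = []
    m = cfg.indel_margin
    for ev in events:
        for _ in range(1000):
            a = int(rng.integers(m, cfg.seq_length - ev["length"] - m))
            iv = (a - m, a + ev["length"] + m)
            if any(max(iv[0], t[0]) < min(iv[1], t[1]) for t in taken):
                continue
            ev["anchor"] = a
            ev["kind"] = "deletion" if rng.random() < 0.5 else "insertion"
            taken.append(iv)
            break
        else:
            raise RuntimeError("could not place indel plan without collisions")
    return events


def simulate(cfg: SimConfig) -> SimResult:
    """Run the generator; same seed gives byte-identical outputs."""
    rng = np.random.default_rng(cfg.seed)
    L0 = cfg.seq_length
    anc = rng.integers(0, 4, size=L0).astype(np.int8)
    planted_repeats = _plant_repeats(anc, cfg.repeat_plan, rng)
    indel_events = _plan_indels(cfg, rng)

    # global alignment columns: ancestral positions with insertion blocks
    insertions = sorted(
        (ev for ev in indel_events if ev["kind"] == "insertion"),
        key=lambda e: e["anchor"],
    )
    anc2col = np.zeros(L0 + 1, dtype=np.int64)
    col_meta: list[tuple[str, int | dict]] = []  # ('anc', pos) | ('ins', event)
    ins_iter = iter(insertions)
    nxt = next(ins_iter, None)
    for pos in range(L0):
        while nxt is not None and nxt["anchor"] == pos:
            nxt["columns"] = (len(col_meta), len(col_meta) + nxt["length"])
            for _ in range(nxt["length"]):
                col_meta.append(("ins", nxt))
            nxt = next(ins_iter, None)
        anc2col[pos] = len(col_meta)
        col_meta.append(("anc", pos))
    anc2col[L0] = len(col_meta)
    n_cols = len(col_meta)
    for ev in indel_events:
        if ev["kind"] == "deletion":
            ev["columns"] = (int(anc2col[ev["anchor"]]),
                            int(anc2col[ev["anchor"] + ev["length"]]))

    wins = window_partition(n_cols, cfg.window_length)
    if cfg.multipliers is not None:
        if len(cfg.multipliers) != len(wins):
            raise ValueError(
                f"{len(cfg.multipliers)} multipliers for {len(wins)} windows"
            )
        mult = np.asarray(cfg.multipliers, dtype=float)
    else:
        shape = cfg.multiplier_gamma_shape
        mult = rng.gamma(shape, 1.0 / shape, size=len(wins))
    col_mult = np.empty(n_cols)
    for (s, e), m in zip(wins, mult):
        col_mult[s:e] = m

    root = np.full(n_cols, -1, dtype=np.int8)
    for c, (kind, payload) in enumerate(col_meta):
        if kind == "anc":
            root[c] = anc[payload]

    by_branch: dict[str, list[dict]] = {}
    for ev in indel_events:
        by_branch.setdefault(ev["branch"], []).append(ev)

    def evolve(parent: np.ndarray, divergence: float, branch: str | None) -> np.ndarray:
        child = parent.copy()
        present = child >= 0
        p_sub = np.clip(divergence * col_mult, 0, 0.75)
        hit = (rng.random(n_cols) < p_sub) & present
        k = int(hit.sum())
        if k:
            child[hit] = (child[hit] + rng.integers(1, 4, size=k).astype(np.int8)) % 4
        for ev in by_branch.get(branch, ()):  # branch indels after substitutions
            s, e = ev["columns"]
            if ev["kind"] == "deletion":
                child[s:e] = -1
            else:
                child[s:e] = rng.integers(0, 4, size=e - s).astype(np.int8)
        return child

    taxa = _make_taxa(cfg)
    lineages = [
        (SPECIES_A, "", "speciesA", cfg.d_s, False),
        (SPECIES_B, VARIETY_B1, "varietyB1", cfg.d_v, True),
        (SPECIES_B, VARIETY_B2, "varietyB2", cfg.d_v, True),
    ]
    spB_anc: np.ndarray | None = None
    leaf_arrays: dict[str, np.ndarray] = {}
    spA_anc = evolve(root, cfg.d_s, "speciesA")
    spB_anc = evolve(root, cfg.d_s, "speciesB")
    for sp, var, branch, div, under_b in lineages:
        if not under_b:
            lin_anc = spA_anc
        else:
            lin_anc = evolve(spB_anc, div, branch)
        members = [sid for sid, row in taxa.rows.items() if row[0] == sp and row[1] == var]
        pops: dict[str, np.ndarray] = {}
        for sid in members:
            pop = taxa.population_of(sid)
            if pop not in pops:
                pops[pop] = evolve(lin_anc, cfg.d_p, f"pop:{pop}")
            leaf_arrays[sid] = evolve(pops[pop], cfg.d_i, f"ind:{sid}")

    def to_string(arr: np.ndarray) -> str:
        out = np.full(n_cols, b"-", dtype="S1")
        present = arr >= 0
        out[present] = _BASE_CODES[arr[present]]
        return out.tobytes().decode("ascii")

    ids = list(taxa.rows)
    aln = Alignment([SequenceRecord(sid, to_string(leaf_arrays[sid])) for sid in ids])
    seqs = [
        SequenceRecord(sid, to_string(leaf_arrays[sid]).replace("-", "")) for sid in ids
    ]

    features = _make_features(cfg, anc2col, aln, ids[0])

    planted = [
        PlantedIndel(
            ev["branch"],
            ev["kind"],
            ev["length"],
            ev["anchor"],
            tuple(ev["columns"]),
            _SPECIFICITY_OF_BRANCH.get(ev["branch"], "polymorphic"),
        )
        for ev in indel_events
    ]
    truth = TruthRecord(
        planted_indels=planted,
        planted_repeats=planted_repeats,
        multipliers=[float(m) for m in mult],
        windows=wins,
        groups={
            "species": {k: v for k, v in taxa.groups("species").items()},
            "variety": {k: v for k, v in taxa.groups("variety").items()},
        },
    )
    anc_str = _BASE_CODES[anc].tobytes().decode("ascii")
    return SimResult(seqs, aln, taxa, features, truth, anc_str)


def _make_features(
    cfg: SimConfig, anc2col: np.ndarray, aln: Alignment, ref_id: str
) -> FeatureTable:
    """Gene-like annotation tiled over the ancestor, projected onto the
    reference individual's ungapped coordinates.

    Each 1200-bp block carries two coding exons flanking an intron; the
    remainder is unannotated (intergenic).
    """
    ref_row = np.frombuffer(aln.row(ref_id).encode(), dtype="S1")
    present = ref_row != b"-"
    prefix = np.concatenate([[0], np.cumsum(present)])  # ref bases before col

    def anc_to_ref(pos: int) -> int:
        return int(prefix[int(anc2col[pos])])

    feats = []
    block = 1200
    g = 0
    for b0 in range(0, cfg.seq_length - block + 1, block):
        g += 1
        for name, cls, s, e in (
            (f"gene{g}_exon1", "CDS", b0 + 150, b0 + 500),
            (f"gene{g}_intron", "intron", b0 + 500, b0 + 600),
            (f"gene{g}_exon2", "CDS", b0 + 600, b0 + 1050),
        ):
            rs, re = anc_to_ref(s), anc_to_ref(e)
            if re > rs:
                feats.append(Feature(ref_id, rs, re, name, cls))
    return FeatureTable(feats)


# analytic expectation oracle used by the test suite ------------------------


def expected_p_distance(
    cfg: SimConfig, path_a: list[float], path_b: list[float], multiplier: float = 1.0
) -> float:
    """Exact per-site mismatch probability between two lineages.

    ``path_a``/``path_b`` list the branch divergences from the shared
    ancestor to each leaf.  Under single-hit-per-branch equal exchange the
    probability a lineage still matches the ancestor evolves as
    q' = q(1-p) + (1-q) p/3, and by symmetry
    P(match) = q1 q2 + (1-q1)(1-q2)/3.
    """
    def q_along(path: list[float]) -> float:
        q = 1.0
        for d in path:
            p = min(d * multiplier, 0.75)
            q = q * (1 - p) + (1 - q) * (p / 3)
        return q

    q1, q2 = q_along(path_a), q_along(path_b)
    return 1.0 - (q1 * q2 + (1 - q1) * (1 - q2) / 3)
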