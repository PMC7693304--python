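"""Stage orchestration from a YAML config: distances -> windows -> trees ->
indels -> repeats, with a run manifest for reproducibility."""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .seq_io import (
    Alignment,
    read_alignment,
    read_features,
    read_fasta,
    read_taxon_table,
)
from .distances import locus_summary, barcoding_gap, summary_table, _LEVEL_CLASSES
from .windows import (
    window_dxy,
    merge_profiles,
    rate_correlation,
    call_hypervariable,
    regions_to_bed,
)
from .distances import distance_matrix
from .trees import (
    bootstrap_trees,
    nj,
    majority_consensus,
    identification_rate,
    write_newick,
)
from .indels import (
    indel_events,
    classify_specificity,
    annotate_context,
    indel_spectrum,
    events_to_frame,
)
from .repeats import find_repeat_pairs, pairs_to_frame

log = logging.getLogger("skimbarcode.pipeline")


@dataclass
class RunConfig:
    alignment: str
    taxon_table: str
    features: str | None = None
    repeat_fasta: str | None = None  # unaligned sequences for repeat search
    molecule: str = "molecule"
    window_length: int = 200
    bootstrap_reps: int = 1000
    seed: int = 0
    min_identity: float = 0.90
    min_repeat_len: int = 30
    threshold_quantile: float = 0.95
    merge_gap: int = 1
    min_support: float = 50
    min_valid_sites: float | None = None
    ref_id: str | None = None
    outdir: str = "results/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for attr in ("alignment", "taxon_table"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        for attr in ("features", "repeat_fasta"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if not (0 <= self.threshold_quantile <= 1):
            raise ValueError("threshold_quantile must be in [0, 1]")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage=%s status=start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.error("stage=%s status=FAILED", name)
                raise RuntimeError(f"stage {name!r} failed") from sys.exc_info()[1]
            log.info("stage=%s status=done elapsed=%.1fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


def run(cfg: RunConfig) -> dict:
    """Execute all stages; writes outputs and a manifest under cfg.outdir.

    Returns a dict of headline numbers (identification rates, gap calls,
    window extremes, indel/repeat counts).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln = read_alignment(cfg.alignment)
    taxa = read_taxon_table(cfg.taxon_table)
    features = read_features(cfg.features) if cfg.features else None
    report: dict = {"molecule": cfg.molecule}

    summary = _run_distances(aln, taxa, cfg, outdir, report)
    profile = _run_windows(aln, taxa, cfg, outdir, report)
    _run_trees(aln, taxa, cfg, outdir, report)
    _run_indels(aln, taxa, features, cfg, outdir, report)
    _run_repeats(cfg, outdir, report)

    manifest = {
        "version": __version__,
        "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        "n_sequences": aln.n_seqs,
        "n_columns": aln.n_cols,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


@_stage("distances")
def _run_distances(aln, taxa, cfg, outdir, report):
    summary = locus_summary(aln, taxa, locus=cfg.molecule)
    df = summary_table([summary])
    df.to_csv(outdir / "distance_summary.tsv", sep="\t", index=False)
    for level in ("species", "variety"):
        b, w = _LEVEL_CLASSES[level]
        if b in summary.per_class and w in summary.per_class:
            gap = barcoding_gap(summary, level)
            report[f"{level}_gap"] = gap.has_gap
            report[f"{level}_gap_width"] = gap.gap_width
    return summary


@_stage("windows")
def _run_windows(aln, taxa, cfg, outdir, report):
    sp_groups = taxa.groups("species", ids=aln.ids)
    prof = window_dxy(
        aln, sp_groups, cfg.window_length,
        level="inter-species", molecule=cfg.molecule,
        min_valid_sites=cfg.min_valid_sites,
    )
    multi = taxa.multi_variety_species()
    if multi:
        var_ids = [i for i in aln.ids if taxa.species_of(i) in multi]
        var_groups = taxa.groups("variety", ids=var_ids)
        vprof = window_dxy(
            aln, var_groups, cfg.window_length,
            level="inter-variety", molecule=cfg.molecule,
            min_valid_sites=cfg.min_valid_sites,
        )
        prof = merge_profiles(prof, vprof)
        report["rate_correlation"] = rate_correlation(
            prof, "inter-species", "inter-variety"
        )
        report["max_rate_inter_variety"] = prof.max_rate("inter-variety")
    report["max_rate_inter_species"] = prof.max_rate("inter-species")
    prof.to_frame().to_csv(outdir / "window_profile.tsv", sep="\t", index=False)
    for level in prof.levels():
        call = call_hypervariable(
            prof, level, cfg.threshold_quantile, cfg.merge_gap
        )
        (outdir / f"hypervariable_{level}.bed").write_text(
            regions_to_bed(call, cfg.molecule)
        )
        report[f"n_hypervariable_{level}"] = len(call.regions)
    return prof


@_stage("trees")
def _run_trees(aln, taxa, cfg, outdir, report):
    dm = distance_matrix(aln)
    tree = nj(dm)
    write_newick(tree, outdir / "nj.nwk")
    boots = bootstrap_trees(aln, cfg.bootstrap_reps, cfg.seed)
    cons = majority_consensus(boots)
    write_newick(cons, outdir / "consensus.nwk")
    for level in ("species", "variety"):
        try:
            res = identification_rate(cons, taxa, level, cfg.min_support)
        except ValueError:
            continue
        report[f"identification_rate_{level}"] = res.rate
    return cons


@_stage("indels")
def _run_indels(aln, taxa, features, cfg, outdir, report):
    events = indel_events(aln)
    ref = cfg.ref_id or aln.ids[0]
    for ev in events:
        classify_specificity(ev, taxa)
        if features is not None:
            annotate_context(ev, features, ref, aln)
    events_to_frame(events).to_csv(outdir / "indels.tsv", sep="\t", index=False)
    spec = indel_spectrum(events)
    spec["table"].to_csv(outdir / "indel_spectrum.tsv", sep="\t", index=False)
    for key in ("species-specific", "variety-specific", "polymorphic"):
        report[f"n_indels_{key}"] = sum(1 for e in events if e.specificity == key)
    report["indel_fraction_le_10bp"] = spec["fraction_le_10bp"]
    report["n_indels_gt_100bp"] = spec["count_gt_100bp"]
    return events


@_stage("repeats")
def _run_repeats(cfg, outdir, report):
    if cfg.repeat_fasta is None:
        report["n_repeat_pairs"] = None
        return None
    seqs = read_fasta(cfg.repeat_fasta)
    all_pairs = []
    for rec in seqs:
        pairs = find_repeat_pairs(
            rec.seq, cfg.min_repeat_len, cfg.min_identity
        )
        df = pairs_to_frame(pairs)
        df.insert(0, "seq_id", rec.id)
        all_pairs.append(df)
    import pandas as pd

    out = pd.concat(all_pairs, ignore_index=True) if all_pairs else pd.DataFrame()
    out.to_csv(outdir / "repeats.tsv", sep="\t", index=False)
    report["n_repeat_pairs"] = int(len(out))
    return out
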