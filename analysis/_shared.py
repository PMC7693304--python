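"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from skimbarcode.seq_io import read_alignment, read_features, read_taxon_table
from skimbarcode.synthetic_data import SimConfig, simulate

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"
SEED = 20260922


def ensure_bundle():
    """Simulated study bundle on disk (generated by 01, regenerated here if
    a later driver is run first)."""
    if not (DATA / "alignment.fasta").exists():
        simulate(SimConfig(seed=SEED)).write_bundle(DATA)
    return {
        "alignment": read_alignment(DATA / "alignment.fasta"),
        "taxa": read_taxon_table(DATA / "taxa.tsv"),
        "features": read_features(DATA / "features.gff3"),
    }
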