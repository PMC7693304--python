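"""Lineage-specific indel screen.

Extracts indel events (maximal runs of identical gap patterns), labels
each as species-specific, variety-specific or polymorphic, annotates its
genomic context from the reference annotation, and summarizes the length
spectrum.  Writes results/indels.tsv and results/indel_spectrum.tsv.
"""

from _shared import RESULTS, ensure_bundle

from skimbarcode.indels import (
    annotate_context,
    classify_specificity,
    events_to_frame,
    indel_events,
    indel_spectrum,
)


def main() -> None:
    d = ensure_bundle()
    aln, taxa, features = d["alignment"], d["taxa"], d["features"]
    ref = aln.ids[0]
    events = indel_events(aln)
    for ev in events:
        classify_specificity(ev, taxa)
        annotate_context(ev, features, ref, aln)
    events_to_frame(events).to_csv(RESULTS / "indels.tsv", sep="\t", index=False)
    spec = indel_spectrum(events)
    spec["table"].to_csv(RESULTS / "indel_spectrum.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / 'indels.tsv'} ({spec['n_events']} events)")
    by = {}
    for e in events:
        by[e.specificity] = by.get(e.specificity, 0) + 1
    for k, v in sorted(by.items()):
        print(f"  {k}: {v}")
    ctx = {}
    for e in events:
        ctx[e.context] = ctx.get(e.context, 0) + 1
    shares = ", ".join(
        f"{k} {100 * v / spec['n_events']:.1f}%" for k, v in sorted(ctx.items())
    )
    print(f"  contexts: {shares}")
    print(f"  {100 * spec['fraction_le_10bp']:.1f}% of events <= 10 bp; "
          f"{spec['count_gt_100bp']} event(s) > 100 bp")


if __name__ == "__main__":
    main()
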