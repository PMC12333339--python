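#!/usr/bin/env python
"""Chemical-space analysis of the synthetic collection.

Places canonical records in the Q-vs-length plane and all records in the
SlogP-vs-MW plane, counts taste classes around the Q rule threshold
(1400 cal/mol) and a logP threshold (-0.20), compares the size and
hydrophobicity correlations, and summarizes BTT bands and receptor
coverage.
"""

from pathlib import Path

import pandas as pd

from bitterspace import read_records
from bitterspace.dataset import (
    AXES_LOGP_MW,
    AXES_Q_LENGTH,
    btt_summary,
    correlation_report,
    export_space_plot,
    length_distribution,
    load_tas2r_reference,
    receptor_coverage,
    space_points,
    split_canonical,
    threshold_enrichment,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
Q_THRESHOLD = 1400.0
LOGP_THRESHOLD = -0.20


def main() -> None:
    records = read_records(RESULTS / "bps_synthetic.tsv")
    canonical, _ = split_canonical(records)

    length_distribution(canonical).to_csv(
        RESULTS / "length_distribution.tsv", sep="\t", index=False)

    q_pts, q_excl = space_points(records, AXES_Q_LENGTH)
    lp_pts, _ = space_points(records, AXES_LOGP_MW)
    for pts, name in ((q_pts, "space_q_length"), (lp_pts, "space_logp_mw")):
        pd.DataFrame(
            [{"id": p.id, pts[0].axes[0]: p.x, pts[0].axes[1]: p.y,
              "taste": p.taste, "mod_group": p.mod_group} for p in pts]
        ).to_csv(RESULTS / f"{name}.tsv", sep="\t", index=False)
        export_space_plot(pts, RESULTS / f"{name}.png", color_by="taste")

    q_enrich = threshold_enrichment(q_pts, Q_THRESHOLD)
    lp_enrich = threshold_enrichment(lp_pts, LOGP_THRESHOLD)
    print(f"Q plane: {len(q_pts)} canonical points "
          f"({len(q_excl)} modified records excluded from the Q axis)")
    print(f"  above {Q_THRESHOLD:.0f} cal/mol: {q_enrich.bitter_above} bitter / "
          f"{q_enrich.nonbitter_above} nonbitter "
          f"(bitter fraction {q_enrich.bitter_fraction_above:.2f})")
    print(f"  below: {q_enrich.bitter_below} bitter / {q_enrich.nonbitter_below} "
          f"nonbitter (bitter fraction {q_enrich.bitter_fraction_below:.2f})")
    print(f"logP plane: above {LOGP_THRESHOLD}: {lp_enrich.bitter_above} bitter / "
          f"{lp_enrich.nonbitter_above} nonbitter")

    qmap = {p.id: p for p in q_pts}
    mw_len = [(p.y, qmap[p.id].y) for p in lp_pts if p.id in qmap]
    q_logp = [(qmap[p.id].x, p.x) for p in lp_pts if p.id in qmap]
    r_size, r_hydro, _ = correlation_report(mw_len, q_logp)
    print(f"r(MW, length) = {r_size:.3f}  vs  r(Q, logP) = {r_hydro:.3f}")

    btt = btt_summary(records)
    btt["bands"].to_csv(RESULTS / "btt_bands.tsv", sep="\t", index=False)
    print(f"BTT: {btt['n']} records, fraction below 10 mmol/L = "
          f"{btt['fraction_below_10']:.2f} "
          f"(min {btt['min']['btt_mmol_L']:.3g}, max {btt['max']['btt_mmol_L']:.3g})")

    coverage = receptor_coverage(reference=load_tas2r_reference())
    coverage.to_csv(RESULTS / "receptor_coverage_reference.tsv", sep="\t", index=False)
    top = coverage.iloc[0]
    print(f"reference receptor coverage: {top['receptor']} leads with "
          f"{top['peptide_count']} peptides")


if __name__ == "__main__":
    main()
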