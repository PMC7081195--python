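"""Simulate a serum-miRNA case/control cohort and write chip fixtures.

Builds a 500-probe cohort of 200 lung-cancer and 200 non-cancer samples
with two planted marker miRNAs, writes one chip TSV per sample plus a
metadata CSV, and summarizes chip quality control.
"""

from pathlib import Path

from mirpanel import PlantedMarker, SimConfig, generate_cohort, qc_chip, write_fixtures

cfg = SimConfig(
    seed=1,
    planted_markers=(
        PlantedMarker("miR-0101", "up", 2.0),     # higher in cancer serum
        PlantedMarker("miR-0202", "down", 2.0),   # lower in cancer serum
    ),
)
chips, metas = generate_cohort(cfg)
out = Path("scratch/example_cohort")
write_fixtures(chips, metas, out)

qc = [qc_chip(c) for c in chips]
n_fail = sum(not q.passed for q in qc)
print(f"wrote {len(chips)} chip tables + metadata.csv to {out}/")
print(f"chips failing QC (>10 flags or negative-control CV > 0.15): {n_fail}")
print(f"cancer samples: {sum(m.label == 'cancer' for m in metas)}, "
      f"non-cancer: {sum(m.label == 'non_cancer' for m in metas)}")
# Each chip carries target probes, 3 internal-control miRNAs used for
# normalization, and 100 empty negative-control spots that estimate the
# chip background level.
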