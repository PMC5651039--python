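"""End-to-end replica on a synthetic two-run cohort.

Generates a 20-subject cohort (225 scans at TR 0.645 s and 93 scans at
TR 1.4 s, 20 visual ROIs, five pairs with negative task modulation of
connectivity), runs both PPI methods on both runs, and prints the group
results on the modulated pairs plus the between-run reliability summary.
"""

from ppikit import CohortSpec, StudyConfig, generate_cohort, run_study

dataset = generate_cohort(CohortSpec(n_subjects=20, seed=42))
result = run_study(dataset, StudyConfig())

idx = {label: i for i, label in enumerate(result.roi_labels)}
print("group t (negative contrast) on the five modulated ROI pairs:")
print(f"{'pair':<16}" + "".join(f"{m}/run{r + 1:<6}" for m, r in result.scenario_keys()))
for a, b in dataset.spec.ppi_effects:
    row = "".join(
        f"{result.group_t[key][idx[a], idx[b]]:>12.2f}" for key in result.scenario_keys()
    )
    print(f"{a}--{b:<8}" + row)

conj = result.conjunction
print(f"\nedges in the full 4-scenario conjunction at p < 0.01: {(conj == 4).sum() // 2}")
for method, entry in result.reliability["icc"].items():
    print(f"median edgewise ICC ({method}): {entry['median']:.3f}")
print(
    "\nNegative t values mark reduced connectivity during stimulation; the"
    "\nconjunction counts edges significant in both methods and both runs."
)
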