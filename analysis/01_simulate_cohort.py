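"""Generate the study cohort: 31 subjects x 160 ROIs x 943 time points.

Band-limited (0.01-0.08 Hz, TR 0.475 s) BOLD signals with six planted
communities of sizes 34/21/32/33/22/18.  Subject TSVs and the ground-truth
template go to scratch/cohort/ (large artifacts); the manifest is echoed.
"""

from pathlib import Path

from fcnets import CohortSpec, generate_cohort, write_cohort

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"

if __name__ == "__main__":
    spec = CohortSpec(seed=20)
    cohort = generate_cohort(spec)
    manifest = write_cohort(cohort, OUT)
    print(f"{cohort.n_subjects} subjects, {spec.n_rois} ROIs, "
          f"{spec.n_timepoints} time points -> {OUT}")
    print(f"manifest: {manifest}")
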