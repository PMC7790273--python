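"""Simulate two small independent cohorts and write them to disk.

Each subject gets a raw dual-wavelength optical recording (TSV per
wavelength), a trial/events table with valence-arousal ratings, and a
pre/post mood scale.  The manifest records a sha256 per file, so identical
seeds reproduce byte-identical datasets.
"""

import fnirsdecode as fd

params = fd.scaled_params(n_train=3, n_test=2, seed=11, tasks=("active",))
manifest = fd.simulate_cohorts(params, "scratch/example_cohorts")

print(f"train subjects: {sorted(manifest['cohorts']['train'])}")
print(f"test subjects:  {sorted(manifest['cohorts']['test'])}")
print(f"files written:  {len(manifest['files'])}")
first = sorted(manifest["files"])[0]
print(f"e.g. {first} sha256={manifest['files'][first][:12]}...")
print("Each subject directory holds intensity_760nm.tsv / intensity_850nm.tsv")
print("(strictly positive light intensities), events_active.tsv and mood.tsv.")
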