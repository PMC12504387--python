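"""Generate a small synthetic leaf-disease dataset with planted lesions.

Each image is a textured green background plus one Gaussian lesion blob
whose colour encodes the class; the manifest records the true lesion
centre, so downstream localisation is checkable.
"""

from pathlib import Path

from camricap import SyntheticSpec, generate_dataset

out_dir = Path("scratch/example_dataset")
spec = SyntheticSpec(num_classes=3, seed=0)
manifest = generate_dataset(20, spec, out_dir)

print(f"wrote {len(manifest)} PNGs under {out_dir}")
print(manifest.groupby(["label", "split"]).size().unstack(fill_value=0))
print()
print("Rows per class and split: 16 train / 2 val / 2 test, the stratified")
print("80/10/10 convention. The u, v columns are each lesion's true centre:")
print(manifest.head(3).to_string(index=False))
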