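"""Write a small paired dataset (images + label masks + specs) to disk.

Equivalent to the CLI call
    muscleseg synth --out scratch/demo_data --n 3 --noise medium --seed 42
but done through the library API.
"""

import json
from pathlib import Path

from muscleseg import SyntheticSpec, generate_muscle_image
from muscleseg.io import write_image, write_label_mask

out = Path("scratch/demo_data")
out.mkdir(parents=True, exist_ok=True)

for i in range(3):
    spec = SyntheticSpec(rng_seed=42 + i, noise_level="medium")
    image, labels = generate_muscle_image(spec)
    stem = f"synthetic_{spec.rng_seed:04d}"
    write_image(out / f"{stem}.tiff", image)
    write_label_mask(out / f"{stem}_labels.png", labels)
    (out / f"{stem}_spec.json").write_text(json.dumps(spec.to_dict(), indent=2))
    print(f"{stem}: {labels.n_fibres} fibres, noise={spec.noise_level}")

print(f"\nwrote 9 files to {out}/ — image.tiff / labels.png / spec.json "
      "triplets, ready for `muscleseg segment` and `muscleseg evaluate`")
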