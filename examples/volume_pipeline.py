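"""Full mask-volume pipeline on a staphyloma-like phantom.

Voxelizes a Type-1 phantom (elongated globe + conical posterior
protrusion) at 0.5 mm, writes it as NIfTI, then runs the file-based
pipeline: frame estimation, topography, map rendering and parameters.
Artifacts land in scratch/volume_pipeline_out/.
"""

import json
from pathlib import Path

import scleratopo as st
from scleratopo.io import write_volume
from scleratopo.pipeline import RunConfig, run_pipeline

outdir = Path("scratch/volume_pipeline_out")
outdir.mkdir(parents=True, exist_ok=True)

vol = st.make_volume(st.DEFAULT_TYPE_SPECS[1])
mask_path = write_volume(vol, outdir / "type1_mask.nii.gz")

artifacts = run_pipeline(
    RunConfig(input=str(mask_path), anterior_hint="-y", outdir=str(outdir))
)
params = json.loads(artifacts["params"].read_text())
print("artifacts:", ", ".join(str(v) for v in artifacts.values()))
print(f"D_var  = {params['D_var']:.3f} mm^2   (posterior asphericity; ~0.6 Type 0, ~5 Type 2)")
print(f"CD_max = {params['CD_max']:.3f}        (combined elongation+sharpness; ~1 normal eye)")
print("The topo.png map shows D and C over the posterior 120°; the central")
print("hot spot is the conical protrusion at the posterior pole.")
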