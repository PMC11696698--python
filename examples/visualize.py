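"""Plot estimated cell-type compositions on the tissue layout.

Writes a scatter-pie overview (one pie per spot, wedge angles = estimated
composition) and per-type proportion maps (fixed 0-1 color scale) for a
simulated tissue.
"""

from pathlib import Path

import spotdeconv as sd

outdir = Path("scratch/figures")
outdir.mkdir(parents=True, exist_ok=True)

cfg = sd.SimulationConfig(noise_model="poisson", seed=5)
ref, spatial, _ = sd.generate_dataset(cfg)
ref_pp, spatial_pp = sd.preprocess(*sd.align_genes(ref, spatial))
res = sd.run_sls(ref_pp, spatial_pp)

sd.overall_plot(res.proportions, spatial_pp.coordinates, path=outdir / "overall.png")
sd.separate_plot(res.proportions, spatial_pp.coordinates, path=outdir / "separate.png")
print(f"wrote {outdir/'overall.png'} and {outdir/'separate.png'}")
print("each pie shows one spot's estimated mixture; the separate panels show")
print("where each cell type concentrates, on a common 0-1 proportion scale")
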