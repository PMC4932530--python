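"""Prepare modelling inputs: snap/thin occurrences to the grid, apply the
more-than-ten-records rule, and screen the predictors for collinearity
(|Pearson r| > 0.8 on a 10,000-point background sample).
"""

from pathlib import Path

from bryoclim.workflow import load_config, run

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "run"  # raster-heavy artifacts stay out of results/

state = run(load_config(ROOT / "configs" / "demo.yaml"), OUT, upto="prepare")

print(f"retained predictors: {', '.join(state.retained_vars)}")
for dropped, kept, r in state.screen.dropped:
    print(f"  dropped {dropped} (r={r:+.3f} with {kept})")
for name, occ in state.occurrences.items():
    print(f"  {name}: {len(occ)} thinned cells (passes minimum-records rule)")
for name, reason in state.excluded.items():
    print(f"  excluded {name}: {reason}")
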