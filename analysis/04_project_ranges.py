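"""Project each consensus model onto present and 2070-style scenario
climates, flag non-analog cells with MESS, binarize at the 5%-omission
threshold, and mask non-analog areas out of the binary ranges.
"""

from pathlib import Path

from bryoclim.workflow import load_config, run

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "run"  # raster-heavy artifacts stay out of results/

state = run(load_config(ROOT / "configs" / "demo.yaml"), OUT, upto="project")

scenarios = ["present"] + [d.label for d in state.config.scenarios]
for name in state.ensembles:
    thr = state.thresholds_used[name]
    omission = state.ranges[(name, "present")].omission
    print(f"{name}: threshold {thr:.3f} (calibration omission {omission:.3f})")
    for scen in scenarios:
        br = state.ranges[(name, scen)]
        analog = int(state.mess[(name, scen)].analog.sum())
        print(f"  {scen:8s} suitable cells {br.n_cells:5d}  analog cells {analog:5d}")
print(f"surfaces -> {OUT / 'surfaces'}")
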