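"""Fit the three techniques per species (climatic envelope, penalized
presence-background model, random forest), evaluate each by ten 70/30
splits with AUC and TSS, drop failures (AUC < 0.8 or TSS < 0.7), and
build the AUC-weighted consensus.
"""

from pathlib import Path

from bryoclim.workflow import load_config, run

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "run"  # raster-heavy artifacts stay out of results/

state = run(load_config(ROOT / "configs" / "demo.yaml"), OUT, upto="fit")

for name, evs in state.evaluations.items():
    print(name)
    for ev in evs:
        flag = "pass" if ev.passed else "ELIMINATED"
        print(f"  {ev.technique:13s} mean AUC {ev.mean_auc:.3f}  mean TSS {ev.mean_tss:.3f}  {flag}")
    ens = state.ensembles.get(name)
    if ens is not None:
        w = ", ".join(f"{m.technique}={wt:.3f}" for m, wt in zip(ens.members, ens.weights))
        print(f"  consensus weights: {w}")
for name, reason in state.excluded.items():
    print(f"excluded {name}: {reason}")
print(f"evaluation table -> {OUT / 'models' / 'evaluation.csv'}")
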