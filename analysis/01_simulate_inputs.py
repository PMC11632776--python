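"""Generate the synthetic "virtual material" every later step analyses.

Emits, under scratch/virtual_material/, the full input set in the exact
on-disk formats the analysis subcommands read: a noisy cooling curve
(Tg 400 K), two-state bond-event series (breakage rate 1/ns), three
deformation directions (E 3 GPa, nu 0.3, plateau 0.15 GPa), sphere packings
at three strains, and a 50-chain Brownian trajectory (D = 1e-6 cm^2/s).
"""

from pathlib import Path

from mdprops.cli import main

ROOT = Path(__file__).resolve().parent.parent
OUTDIR = ROOT / "scratch" / "virtual_material"

if __name__ == "__main__":
    main(
        ["simulate", "--config", str(ROOT / "examples" / "virtual_material.yaml"),
         "--outdir", str(OUTDIR)],
        standalone_mode=False,
    )
    print(f"ground truth: Tg=400 K, k_break=1/ns, E=3 GPa, nu=0.3, D=1e-6 cm^2/s")
    print(f"inputs in {OUTDIR}")
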