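#!/usr/bin/env python
"""Fit the six gain parameters to synthetic MEG repetition effects.

The study's empirical effect magnitudes are not available here, so the
stand-in targets are produced by forward simulation from the reported
best-fit gains plus a small measurement noise, and the fit is asked to
recover them.  Writes the fit result under results/ and prints the
recovered parameters next to the generating values.
"""

from pathlib import Path

from speechimagery.fitting import fit_meg_gains
from speechimagery.io import write_json
from speechimagery.repetition import TABLE_GAINS
from speechimagery.synth import synth_meg_effects

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    empirical = synth_meg_effects(TABLE_GAINS["AI"], TABLE_GAINS["HI"],
                                  noise_sd=0.01, seed=SEED)
    write_json(empirical.to_dict(), RESULTS / "synthetic_meg_effects.json")
    fit = fit_meg_gains(empirical, seed=SEED)
    write_json(fit, RESULTS / "fit_meg.json")

    generating = {
        "g_repeated_AI": TABLE_GAINS["AI"].g_repeated,
        "g_novel_AI": TABLE_GAINS["AI"].g_novel,
        "G_A_AI": TABLE_GAINS["AI"].attentional,
        "g_repeated_HI": TABLE_GAINS["HI"].g_repeated,
        "g_novel_HI": TABLE_GAINS["HI"].g_novel,
        "G_A_HI": TABLE_GAINS["HI"].attentional,
    }
    print(f"{'parameter':16s} {'generating':>10s} {'recovered':>10s}")
    for name, value in generating.items():
        print(f"{name:16s} {value:10.3f} {fit.params[name]:10.3f}")
    print(f"objective {fit.objective:.3e}; chi2({fit.df}) = {fit.chisq:.4f},"
          f" p = {fit.p_value:.3f}")
    print("note: the four effects pin g_repeated and G_A per task; g_novel "
          "is not identified by this design (see docs/methods.md)")


if __name__ == "__main__":
    main()
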