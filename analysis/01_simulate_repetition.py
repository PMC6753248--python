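#!/usr/bin/env python
"""Simulate the baseline auditory response and the imagery repetition
effects with the reported best-fit gains.

Writes the baseline waveform dump and the four percentage changes under
results/, and prints what the simulation found: where the summed
phonological response peaks and how each imagery condition moves the
windowed response relative to baseline.
"""

from pathlib import Path

from speechimagery.io import write_json
from speechimagery.network import StimulusProtocol, simulate
from speechimagery.repetition import TABLE_GAINS, simulate_repetition_effects

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    baseline = simulate(StimulusProtocol.constant("ba", 1.0, 0.0, 500.0),
                        require_peak=True)
    frame = baseline.to_frame().round(5)
    frame[["time_ms", "summed_phonological"]].to_csv(
        RESULTS / "baseline_summed_waveform.csv", index=False)
    print(f"baseline summed waveform peaks at {baseline.peak_latency_ms:.0f} "
          f"ms after onset (25-ms window mean {baseline.peak_window_mean:.4f})")

    effects = simulate_repetition_effects(TABLE_GAINS["AI"],
                                          TABLE_GAINS["HI"])
    write_json(effects.to_dict(), RESULTS / "repetition_effects.json")
    for name in ("ai_repeated", "ai_novel", "hi_repeated", "hi_novel"):
        print(f"  {name:12s} {getattr(effects, name) * 100:+6.2f}% vs baseline")
    print("articulation imagery shows repetition enhancement "
          f"(repeated {'>' if effects.ai_repeated > effects.ai_novel else '<'}"
          " novel); see docs/methods.md for why hearing-imagery suppression "
          "does not emerge from the printed constants")


if __name__ == "__main__":
    main()
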