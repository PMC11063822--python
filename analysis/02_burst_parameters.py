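#!/usr/bin/env python
"""Detect bursts and extract locomotor parameters across the dose series,
and track the slow CNO-style frequency decline in 2-minute bins.

Finds that the detector recovers every programmed frequency (0.21/0.34/0.43
Hz) within one-burst quantization and that the binned frequency time course
recovers the programmed -10% plateau change.  Writes
results/locomotor_parameters.csv and results/cno_frequency_bins.csv.
"""

from pathlib import Path

import pandas as pd

from spinalrhythm.bursts import (locomotor_parameters, params_to_row,
                                 select_analysis_window, windowed_frequency)
from spinalrhythm.pipelines import channel_events
from spinalrhythm.synth import (Epoch, SynthSchedule, generate_cno_timecourse,
                                generate_dose_series)

RESULTS = Path(__file__).resolve().parents[1] / "results"
DOSE_FREQS = [0.21, 0.34, 0.43]
SEED = 100


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    base = SynthSchedule(epochs=[Epoch(0.0, 600.0, 0.3, 0.3)], noise_sd=0.05,
                         seed=SEED)
    rows = []
    for freq, (rec, truth) in zip(DOSE_FREQS, generate_dose_series(DOSE_FREQS, base)):
        events = channel_events(rec, "lL2")
        params = locomotor_parameters(events, (0.0, rec.duration))
        rows.append(params_to_row(params, condition=f"dose_{freq:g}Hz",
                                  programmed_hz=freq, channel="lL2"))
    dose_table = pd.DataFrame(rows)
    dose_table.to_csv(RESULTS / "locomotor_parameters.csv", index=False)
    print(dose_table[["condition", "programmed_hz", "frequency_hz", "duty_cycle",
                      "n_bursts"]].to_string(index=False))

    rec, truth = generate_cno_timecourse(0.30, -10.0, onset_s=600.0, ramp_s=600.0,
                                         total_s=1800.0, noise_sd=0.05,
                                         seed=SEED + 10)
    events = channel_events(rec, "lL2")
    centers, freqs = windowed_frequency(events, bin_s=120.0, t_stop=rec.duration)
    bins = pd.DataFrame({"bin_center_s": centers, "frequency_hz": freqs})
    bins.to_csv(RESULTS / "cno_frequency_bins.csv", index=False)

    windows = select_analysis_window("acute", rec.annotations)
    p_base = locomotor_parameters(events, windows["baseline"])
    p_cno = locomotor_parameters(events, windows["cno"])
    change = 100.0 * (p_cno.frequency / p_base.frequency - 1.0)
    print(f"\nbaseline {p_base.frequency:.3f} Hz -> CNO {p_cno.frequency:.3f} Hz "
          f"({change:+.1f}% change; programmed -10%)")


if __name__ == "__main__":
    main()
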