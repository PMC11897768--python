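"""Readers and writers for spike sets and ground-truth tables.

Two on-disk layouts are supported for trial-aligned spike times:

* a long-format CSV with columns
  ``unit_id, condition, tissue, trial, spike_time_s`` — human-greppable
  and diff-friendly;
* an HDF5 layout with one group per unit (attrs: condition, tissue) and
  one dataset per trial (``trial_000`` ...), for larger recordings.

Ground truth of synthetic populations round-trips as JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np

from .stimulus import build_chirp
from .synthetic import SpikeTrainSet, SyntheticUnit, UnitGroundTruth

__all__ = [
    "write_spikes_csv",
    "read_spikes_csv",
    "write_spikes_hdf5",
    "read_spikes_hdf5",
    "write_ground_truth_json",
    "read_ground_truth_json",
]


def write_spikes_csv(spike_set: SpikeTrainSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["unit_id", "condition", "tissue", "trial", "spike_time_s"])
        for unit in spike_set.units:
            for trial_idx, spikes in enumerate(unit.trials):
                for t in spikes:
                    w.writerow(
                        [unit.unit_id, unit.condition, unit.tissue, trial_idx, f"{t:.6f}"]
                    )


def read_spikes_csv(
    path: str | Path,
    n_trials: int,
    sample_rate: float = 1000.0,
    irradiance_log: float = 16.97,
) -> SpikeTrainSet:
    """Read a long-format spike CSV back into a :class:`SpikeTrainSet`.

    Empty trials leave no CSV rows, so the trial count must be supplied.
    """
    per_unit: dict[str, dict] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            uid = row["unit_id"]
            rec = per_unit.setdefault(
                uid,
                {
                    "condition": row["condition"],
                    "tissue": row["tissue"],
                    "trials": {},
                },
            )
            rec["trials"].setdefault(int(row["trial"]), []).append(
                float(row["spike_time_s"])
            )
    units = []
    for uid, rec in per_unit.items():
        trials = [
            np.sort(np.asarray(rec["trials"].get(k, []), dtype=float))
            for k in range(n_trials)
        ]
        units.append(
            SyntheticUnit(
                unit_id=uid,
                condition=rec["condition"],
                tissue=rec["tissue"],
                trials=trials,
            )
        )
    stim = build_chirp(sample_rate, irradiance_log)
    return SpikeTrainSet(units=units, stimulus=stim, n_trials=n_trials)


def write_spikes_hdf5(spike_set: SpikeTrainSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_trials"] = spike_set.n_trials
        f.attrs["irradiance_log"] = spike_set.stimulus.irradiance_log
        f.attrs["sample_rate"] = spike_set.stimulus.sample_rate
        for unit in spike_set.units:
            g = f.create_group(unit.unit_id)
            g.attrs["condition"] = unit.condition
            g.attrs["tissue"] = unit.tissue
            for k, spikes in enumerate(unit.trials):
                g.create_dataset(f"trial_{k:03d}", data=np.asarray(spikes, dtype=float))


def read_spikes_hdf5(path: str | Path) -> SpikeTrainSet:
    with h5py.File(path, "r") as f:
        n_trials = int(f.attrs["n_trials"])
        stim = build_chirp(float(f.attrs["sample_rate"]), float(f.attrs["irradiance_log"]))
        units = []
        for uid in sorted(f.keys()):
            g = f[uid]
            trials = [np.asarray(g[f"trial_{k:03d}"]) for k in range(n_trials)]
            units.append(
                SyntheticUnit(
                    unit_id=uid,
                    condition=str(g.attrs["condition"]),
                    tissue=str(g.attrs["tissue"]),
                    trials=trials,
                )
            )
    return SpikeTrainSet(units=units, stimulus=stim, n_trials=n_trials)


def write_ground_truth_json(spike_set: SpikeTrainSet, path: str | Path) -> None:
    table = {}
    for unit in spike_set.units:
        gt = unit.ground_truth
        if gt is None:
            continue
        d = {
            "w_on": gt.polarity_weights[0],
            "w_off": gt.polarity_weights[1],
            "latency_s": gt.latency_s,
            "transience_tau_s": gt.transience_tau_s,
            "c50_true": gt.c50_true,
            "nr_slope_true": gt.nr_slope_true,
            "peak_tf_true": gt.peak_tf_true,
            "tf_spread_true": gt.tf_spread_true,
            "hill_ec50_log": gt.hill_ec50_log,
            "hill_slope": gt.hill_slope,
            "baseline_rate": gt.baseline_rate,
            "gain": gt.gain,
            "reliability": gt.reliability,
        }
        table[unit.unit_id] = d
    Path(path).write_text(json.dumps(table, indent=2, sort_keys=True))


def read_ground_truth_json(path: str | Path) -> dict[str, UnitGroundTruth]:
    raw = json.loads(Path(path).read_text())
    out = {}
    for uid, d in raw.items():
        out[uid] = UnitGroundTruth(
            polarity_weights=(d["w_on"], d["w_off"]),
            latency_s=d["latency_s"],
            transience_tau_s=d["transience_tau_s"],
            c50_true=d["c50_true"],
            nr_slope_true=d["nr_slope_true"],
            peak_tf_true=d["peak_tf_true"],
            tf_spread_true=d["tf_spread_true"],
            hill_ec50_log=d["hill_ec50_log"],
            hill_slope=d["hill_slope"],
            baseline_rate=d["baseline_rate"],
            gain=d["gain"],
            reliability=d["reliability"],
        )
    return out
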