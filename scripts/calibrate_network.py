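"""Reproduce the calibration measurements behind the frozen neuron constants.

Three phenomenological targets anchor the free channel constants of the
network's neuron models:

* somatic subthreshold fluctuations of ~3 mV in excitatory neurons under
  background noise alone,
* an inhibitory baseline firing rate of ~10 Hz,
* a dendritic calcium spike lasting ~5 ms.

Run from the repository root:

    python scripts/calibrate_network.py [--seed 1]
"""

from __future__ import annotations

import argparse

import numpy as np

from repeatloop.network import build_network, reduced_config, run_trial


def noise_only_statistics(seed: int) -> dict:
    """Soma fluctuation s.d., dendrite s.d., spontaneous rates (no stimulus)."""
    cfg = reduced_config(
        chains=("a",), topology={"a": ()}, feedback_matrix={}, branch_strength={},
        init_current=0.0, max_duration_ms=2000.0,
    )
    net = build_network(cfg, seed=seed)
    res = run_trial(net, seed=seed + 1)
    m = res.trace_times_ms > 200  # discard the settling transient
    dur_s = (res.duration_ms - 200) / 1000.0
    ids, ts = res.raster.neuron_ids, res.raster.times_ms
    late = ts > 200
    ne, ni = net.n_excitatory, net.n_inhibitory
    return {
        "soma_sd_mV": float(res.trace_vs[m].std()),
        "dend_sd_mV": float(res.trace_vd[m].std()),
        "exc_rate_hz": float(np.sum(late & (ids < ne)) / ne / dur_s),
        "inh_rate_hz": float(np.sum(late & (ids >= ne)) / ni / dur_s),
    }


def burst_statistics(seed: int) -> dict:
    """Dendritic burst duration and pool-to-pool latency in a quiet chain."""
    cfg = reduced_config(
        chains=("a",), topology={"a": ()}, feedback_matrix={}, branch_strength={},
        noise_rate=0.0, drive_rate=0.0, max_duration_ms=100.0,
    )
    net = build_network(cfg, seed=seed)
    first = int(net.neurons_of("a", 1)[0])  # pool 1: driven synaptically
    res = run_trial(net, seed=seed + 1, trace_dt_ms=0.1, trace_neuron=first)
    above = res.trace_times_ms[res.trace_vd > -45.0]
    burst_ms = float(above.max() - above.min()) if above.size > 1 else 0.0
    # pool-to-pool latency from first spike per pool
    ids, ts = res.raster.neuron_ids, res.raster.times_ms
    firsts = []
    for p in range(cfg.pools_per_chain):
        mem = net.neurons_of("a", p)
        mask = np.isin(ids, mem)
        if mask.any():
            firsts.append(ts[mask].min())
    latency = float(np.median(np.diff(firsts))) if len(firsts) > 2 else float("nan")
    return {"ca_spike_ms": burst_ms, "pool_latency_ms": latency,
            "pools_active": len(firsts)}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    noise = noise_only_statistics(args.seed)
    burst = burst_statistics(args.seed)
    print("noise-only network (no stimulus):")
    for k, v in noise.items():
        print(f"  {k:14s} {v:8.2f}")
    print("quiet single chain (no noise):")
    for k, v in burst.items():
        print(f"  {k:14s} {v:8.2f}")
    print("targets: soma_sd ~3 mV, inh_rate ~10 Hz, exc_rate ~0, ca_spike ~5 ms")


if __name__ == "__main__":
    main()
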