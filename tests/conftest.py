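import numpy as np
import pytest

import pausekin as pk


@pytest.fixture(scope="session")
def em_default():
    return pk.EmissionParams()


@pytest.fixture(scope="session")
def small_experiment(em_default):
    """40 traces at 80 uM, 300 s records: shared across analysis tests."""
    scheme = pk.build_default_scheme(ntp=80.0)
    traces, truth = pk.simulate_experiment(
        scheme, 40, 300.0, em_default, seed=5, t_injection=20.0
    )
    return traces, truth


@pytest.fixture(scope="session")
def segmented_experiment(small_experiment):
    """Selection + FRET + HMM + filter + calibration on the shared set."""
    from pausekin.segment import _trace_window, segment_mean_levels

    traces, truth = small_experiment
    kept, _ = pk.select_traces(traces)
    frets = [pk.compute_fret(t) for t in kept]
    segs = pk.segment_hmm(frets, max_states=4, seed=0)
    filtered = []
    for ft, sg in zip(frets, segs):
        base = ft.E[:100][ft.mask[:100]]
        sig = pk.allan_deviation(base, 5) if len(base) >= 10 else 0.02
        filtered.append(pk.filter_steps(sg, sig))
    seg_means = [segment_mean_levels(ft, sg)[0] for ft, sg in zip(frets, filtered)]
    all_e = np.concatenate([_trace_window(ft) for ft in frets])
    levels = pk.fit_fret_levels(
        np.concatenate(seg_means), frame_values=all_e, min_samples_per_peak=30
    )
    paths = [pk.map_states(sg, levels) for sg in filtered]
    return {
        "traces": traces,
        "truth": truth,
        "kept": kept,
        "frets": frets,
        "raw_segments": segs,
        "filtered": filtered,
        "levels": levels,
        "paths": paths,
    }
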