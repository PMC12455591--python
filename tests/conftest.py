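import numpy as np
import pytest

from repliq.config import SyntheticConfig
from repliq.genomic import GenomeLayout
from repliq.simulate import simulate_study


@pytest.fixture(scope="session")
def default_study():
    """The full default synthetic study (2 x 20 Mb, seed 1); shared across
    tests because generation takes a few seconds."""
    return simulate_study(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A 2 x 5 Mb config with proportionally scaled element counts."""
    return SyntheticConfig(seed=3).scaled_to(5)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def corrected_chip(default_study):
    """Knockout-corrected track for the default study (common-peak route)."""
    from repliq.chip import knockout_correct

    return knockout_correct(default_study.chip.control, default_study.chip.ko)


@pytest.fixture(scope="session")
def zone_analysis(default_study):
    """Zones called and classified from the default study's EdU coverage."""
    import numpy as np

    from repliq import zones as Z
    from repliq.config import RunConfig

    rcfg = RunConfig()
    edu = {
        f"{cond}_rep{i + 1}": t
        for cond in ("control", "ko")
        for i, t in enumerate(default_study.eduhu[cond])
    }
    peak_sets = [
        Z.threshold_call_peaks(t, rcfg.peak_z, rcfg.peak_min_run)
        for _, t in sorted(edu.items())
    ]
    zones = Z.call_zones(peak_sets, rcfg.merge_gap, rcfg.min_size)
    counts = Z.count_reads_in_intervals(zones, edu)
    design = {n: ("ko" if n.startswith("ko") else "control") for n in edu}
    libs = {n: float(t.values().sum()) for n, t in edu.items()}
    stats = Z.zone_statistics(zones, counts, design, lib_sizes=libs)
    classified = Z.classify_zones(
        stats, rcfg.conc_min, rcfg.lfc_min, rcfg.zone_fdr_max
    )
    return {
        "zones": zones,
        "counts": counts,
        "classified": classified,
        "libs": libs,
        "edu": edu,
    }


@pytest.fixture(scope="session")
def rt_analysis(default_study):
    """Per-replicate RTI tracks and differential bins for the default study."""
    from repliq import timing as T

    rtis = {
        cond: [T.rti_track(e, l) for e, l in default_study.repliseq[cond]]
        for cond in ("control", "ko")
    }
    bins = T.differential_rt(rtis["control"], rtis["ko"])
    return {"rtis": rtis, "bins": bins}


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
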