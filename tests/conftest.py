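import numpy as np
import pandas as pd
import pytest

from chipxpr import synthio
from chipxpr.pipeline import PipelineConfig, run, scenario_recovery


def random_peaks(rng, n, chroms=("chr1", "chr2"), span=100_000,
                 prefix="p") -> pd.DataFrame:
    """Random valid peak table (summits resolved) for fixtures."""
    summit = rng.integers(300, span - 300, size=n)
    half = rng.integers(50, 250, size=n)
    start = np.maximum(summit - half, 0)
    end = summit + half
    return pd.DataFrame({
        "chrom": rng.choice(chroms, size=n),
        "start": start, "end": end,
        "name": [f"{prefix}{i}" for i in range(n)],
        "score": rng.integers(0, 1000, size=n),
        "strand": ".",
        "signal": rng.uniform(0, 50, size=n).round(3),
        "p": rng.uniform(0, 100, size=n).round(3),
        "q": rng.uniform(0, 100, size=n).round(3),
        "summit_offset": summit - start,
        "summit": summit,
    })


@pytest.fixture(scope="session")
def scenario():
    """One default synthetic scenario shared across the session."""
    return synthio.build_scenario(seed=1)


@pytest.fixture(scope="session")
def scenario_report(scenario, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("scenario")
    paths = synthio.write_scenario(scenario, outdir)
    config = PipelineConfig.from_yaml(paths["config"])
    return run(config)


@pytest.fixture(scope="session")
def recovery_metrics(scenario, scenario_report):
    return scenario_recovery(scenario, scenario_report)
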