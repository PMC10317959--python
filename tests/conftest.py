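import numpy as np
import pandas as pd
import pytest

from crisprtile import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimulationConfig:
    return sd.SimulationConfig(n_regions=20, guides_per_region=4, depth=1000.0, seed=11)


@pytest.fixture(scope="session")
def toy_library() -> pd.DataFrame:
    """Four experimental regions x 4 guides plus a few controls."""
    rows = []
    for r in range(4):
        for g in range(4):
            rows.append(
                {
                    "guide_id": f"UR{r:03d}_g{g + 1:02d}",
                    "protospacer": "A" * 20,
                    "strand": "+",
                    "chrom": "chr1",
                    "target_pos": 1000 * r + 20 * g,
                    "union_id": f"UR{r:03d}",
                    "distance_to_summit": 20 * g - 30,
                    "pool": "pool1",
                    "control_class": "",
                }
            )
    for cc, n in (("NT", 9), ("PL", 4)):
        for k in range(n):
            rows.append(
                {
                    "guide_id": f"{cc}_{k:03d}",
                    "protospacer": "C" * 20,
                    "strand": "+",
                    "chrom": "",
                    "target_pos": -1,
                    "union_id": "",
                    "distance_to_summit": 0,
                    "pool": "control",
                    "control_class": cc,
                }
            )
    return pd.DataFrame(rows)


def make_counts(
    alphas: dict[str, float],
    guides: list[str],
    cell_lines: tuple[str, ...] = ("MPM1",),
    replicates: int = 2,
    timepoints: tuple[int, ...] = (0, 8, 15, 22),
    depth: float = 1000.0,
    dispersion: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Small NB count matrix around exponential dropout, for unit tests."""
    rng = np.random.default_rng(seed)
    data = {}
    a = np.array([alphas[g] for g in guides])
    for cl in cell_lines:
        for rep in range(1, replicates + 1):
            day0 = sd._nb_draw(rng, np.full(len(guides), depth), dispersion)
            for t in timepoints:
                col = f"{cl}_rep{rep}_day{t}"
                if t == 0:
                    data[col] = day0
                else:
                    data[col] = sd._nb_draw(rng, depth * np.exp(a * t), dispersion)
    return pd.DataFrame(data, index=pd.Index(guides, name="guide_id"))
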