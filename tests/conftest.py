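import numpy as np
import pytest

from rer_escape.pipeline import PipelineConfig, run_all
from rer_escape.simulate import SyntheticConfig, generate_fixture


def make_pipeline_config(paths: dict, cfg: SyntheticConfig, out_dir) -> PipelineConfig:
    return PipelineConfig(
        peaks=dict(paths["peaks"]),
        n_early_stages=len(cfg.embryo_stages),
        me3_track=paths["me3"],
        me1_track=paths["me1"],
        conservation_track=paths["conservation"],
        genes=paths["genes"],
        genome=paths["genome"],
        motifs=paths["motifs"],
        expression_groups=paths["expression_groups"],
        expression_stages=paths["expression_stages"],
        seed=cfg.seed,
        out_dir=str(out_dir),
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic bundle plus a full pipeline run over it."""
    root = tmp_path_factory.mktemp("bundle")
    cfg = SyntheticConfig(seed=1)
    paths, truth = generate_fixture(cfg, root / "fixture")
    pcfg = make_pipeline_config(paths, cfg, root / "results")
    report = run_all(pcfg)
    return {
        "cfg": cfg,
        "paths": paths,
        "truth": truth,
        "pipeline_cfg": pcfg,
        "report": report,
        "results_dir": root / "results",
    }


def synthetic_region_catalog(n: int, median: float, seed: int):
    """Synthetic stand-in for a published region catalog.

    Builds ``n`` intervals whose width median equals ``median`` exactly by
    construction (widths drawn log-normal around the median, then the central
    order statistic(s) pinned).  A stand-in for supplementary region lists
    that cannot be redistributed; only the (count, median) summary is
    meaningful.
    """
    from rer_escape.regions import GenomicInterval

    rng = np.random.default_rng(seed)
    widths = np.rint(rng.lognormal(np.log(median), 0.4, size=n)).astype(int)
    widths = np.maximum(widths, 10)
    widths.sort()
    mid = n // 2
    # pin the central order statistic(s) so the sample median is exact
    if n % 2:
        widths[:mid] = np.minimum(widths[:mid], int(np.floor(median)))
        widths[mid] = int(median)
        widths[mid + 1 :] = np.maximum(widths[mid + 1 :], int(np.ceil(median)))
    else:
        lo = int(np.floor(median))
        hi = int(2 * median - lo)
        widths[: mid - 1] = np.minimum(widths[: mid - 1], lo)
        widths[mid - 1], widths[mid] = lo, hi
        widths[mid + 1 :] = np.maximum(widths[mid + 1 :], hi)
    rng.shuffle(widths)
    intervals = []
    pos = 1000
    for i, w in enumerate(widths):
        intervals.append(
            GenomicInterval("chr1", pos, pos + int(w), name=f"region_{i + 1:04d}")
        )
        pos += int(w) + 500
    return intervals
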