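import numpy as np
import pandas as pd
import pytest

from stopover.morphometrics import smi_by_sex
from stopover.synthetic_data import (
    CommunityScenario,
    simulate_community,
    simulate_metadata,
)

TOY_TREE = "((A:1,B:1):1,C:2);"
TOY_TREE4 = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture(scope="session")
def toy_tree() -> str:
    return TOY_TREE


@pytest.fixture(scope="session")
def toy_tree4() -> str:
    return TOY_TREE4


@pytest.fixture(scope="session")
def cohort():
    """Metadata for a mixed-sex cohort with SMI filled (fixed seed)."""
    meta = simulate_metadata(20, 12, seed=11, condition_date_slope=-3.0)
    return smi_by_sex(meta)


@pytest.fixture(scope="session")
def community(cohort):
    """A small community with planted sex / date / condition effects."""
    taxa = [f"ASV{i + 1:04d}" for i in range(60)]
    rng = np.random.default_rng(42)
    base = rng.normal(0.0, 1.5, size=60)
    base[5] = base[10] = base[11] = 1.0  # effect taxa kept comfortably abundant
    scn = CommunityScenario(
        seed=7,
        n_samples=len(cohort),
        n_taxa=60,
        base_log_abundance=base,
        dispersion=60.0,
        sex_effect_taxa={taxa[10]: 2.0, taxa[11]: 2.0},
        date_evenness_slope=-0.04,
        condition_taxon=taxa[5],
        condition_taxon_slope=-1.0,
        depth_range=(14523, 40000),
        n_controls=3,
        n_contaminants=4,
        n_offenders=4,
    )
    table, taxonomy, newick, truth = simulate_community(scn, cohort)
    return {"table": table, "taxonomy": taxonomy, "newick": newick, "truth": truth,
            "scenario": scn, "meta": cohort}


def null_community(seed: int, n_samples: int = 30, n_taxa: int = 40,
                   depth=(5000, 8000), dispersion: float = 60.0):
    """Exchangeable community (no planted effects) plus its metadata."""
    nf = n_samples // 2
    meta = simulate_metadata(nf, n_samples - nf, seed=seed)
    scn = CommunityScenario(
        seed=seed + 90000,
        n_samples=n_samples,
        n_taxa=n_taxa,
        dispersion=dispersion,
        depth_range=depth,
        n_controls=0,
        n_contaminants=0,
    )
    table, _, newick, _ = simulate_community(scn, meta)
    return table.counts, meta, newick
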