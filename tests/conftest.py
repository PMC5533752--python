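import numpy as np
import pytest

from nmrmarker import chemometrics as chem
from nmrmarker import markers as mk
from nmrmarker import preprocess as pre
from nmrmarker import synthdata as syn


@pytest.fixture(scope="session")
def library():
    return syn.build_default_library()


@pytest.fixture(scope="session")
def default_study():
    return syn.simulate_study(seed=1)


def preprocess_matrix(study, sample_type):
    """Exclusion + bucketing + total-area + control-referenced PQN."""
    plan = pre.default_exclusion_plan()
    spectra = study.spectra[sample_type]
    gapped = [pre.apply_exclusions(sp, plan) for sp in spectra]
    meta = study.metadata[study.metadata["sample_type"] == sample_type]
    groups = (
        meta.set_index("sample_id").loc[[sp.sample_id for sp in gapped], "group"].to_numpy()
    )
    bm = pre.bucket_spectra(gapped)
    bm = pre.total_area_normalize(bm)
    bm = pre.pqn_normalize(bm, groups=groups, reference_group="control")
    return bm, groups


def comparison_models(study, library, sample_type, comparison, seed=1):
    """Pareto-scaled OPLS-DA plus volcano table for one comparison."""
    bm, groups = preprocess_matrix(study, sample_type)
    pair = np.isin(groups, [comparison, "control"])
    y = np.where(groups[pair] == comparison, 1.0, -1.0)
    scaler = chem.SpectralScaler(mode="pareto").fit(bm.values[pair])
    X = scaler.transform(bm.values[pair])
    model = chem.OPLSDA(random_state=seed, compute_q2=False).fit(X, y)
    regions = mk.default_quant_regions(library, sample_type)
    quant = mk.quantify_metabolites(bm, regions).loc[np.asarray(bm.sample_ids)[pair]]
    records = mk.build_volcano_table(
        quant, model, bm.edges[scaler.kept_columns_], bm.width, regions,
        groups[pair], comparison, sample_type=sample_type,
    )
    return {
        "bm": bm, "groups": groups[pair], "y": y, "scaler": scaler, "X": X,
        "model": model, "regions": regions, "quant": quant, "records": records,
    }


@pytest.fixture(scope="session")
def serum_smfy(default_study, library):
    """Serum SMFY-vs-control analysis of the seed-1 default study."""
    return comparison_models(default_study, library, "serum", "SMFY")


@pytest.fixture(scope="session")
def serum_gmfs(default_study, library):
    return comparison_models(default_study, library, "serum", "GMFS")
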