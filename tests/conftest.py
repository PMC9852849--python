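import numpy as np
import pandas as pd
import pytest

from coldscreen import PanelConfig, generate_panel, soybean_preset


def make_panel(data: dict, treatment: str = "cold", trial: str = "T1") -> pd.DataFrame:
    """Build a long-format panel from {genotype: {trait: [replicate values]}}."""
    rows = []
    for geno, traits in data.items():
        for trait, values in traits.items():
            for i, v in enumerate(values, start=1):
                rows.append({"genotype": geno, "trial": trial, "replicate": i,
                             "treatment": treatment, "trait": trait, "value": float(v)})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def preset_config():
    return soybean_preset(seed=0)


@pytest.fixture(scope="session")
def preset_panel(preset_config):
    return generate_panel(preset_config)


@pytest.fixture
def single_trait_config():
    """Minimal one-trait config factory with explicit variance components."""
    def _make(n_genotypes=100, n_replicates=3, g_var=5.0, e_var=1.0, seed=0,
              mean=10.0, shift=0.0, **kw):
        return PanelConfig(
            n_genotypes=n_genotypes, n_replicates=n_replicates,
            traits=("Y",), control_means={"Y": mean}, cold_shift={"Y": shift},
            G_cov=[[g_var]], E_cov=[[e_var]], seed=seed,
            control_attenuation=kw.pop("control_attenuation", 0.2), **kw,
        )
    return _make
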