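import numpy as np
import pandas as pd
import pytest

from mesorisk import EffectSpec, GenotypeMatrix, PopulationSample, VariantBlockSpec
from mesorisk import simulate_genotypes, simulate_methylation, simulate_phenotype


def make_genotypes(dosages, chromosome="1", positions=None, ref="A", alt="G"):
    """Construct a GenotypeMatrix from a raw (samples x variants) array."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    positions = positions if positions is not None else [100 * (j + 1) for j in range(m)]
    chroms = [chromosome] * m if isinstance(chromosome, str) else list(chromosome)
    refs = [ref] * m if isinstance(ref, str) else list(ref)
    alts = [alt] * m if isinstance(alt, str) else list(alt)
    variants = pd.DataFrame(
        {"chromosome": chroms, "position": positions, "ref": refs, "alt": alts},
        index=pd.Index([f"v{j}" for j in range(m)], name="variant_id"),
    )
    return GenotypeMatrix(
        samples=[f"S{i:04d}" for i in range(n)], variants=variants, dosages=d
    )


def make_cohort(status, age=None, sex=None, exposure=None, samples=None):
    status = np.asarray(status, dtype=int)
    n = len(status)
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        {
            "status": status,
            "age": age if age is not None else rng.normal(60, 10, n).round(1),
            "sex": sex if sex is not None else np.where(rng.random(n) < 0.5, "M", "F"),
            "exposure": pd.array(
                exposure if exposure is not None else rng.integers(0, 3, n), dtype="Int64"
            ),
        },
        index=pd.Index(samples or [f"S{i:04d}" for i in range(n)], name="sample_id"),
    )


@pytest.fixture
def toy_genotypes():
    return make_genotypes([[0, 1], [1, 2], [2, 0]])


@pytest.fixture
def small_population():
    """~600-sample population with genetic, exposure and methylation effects."""
    blocks = [
        VariantBlockSpec(n_variants=20, ld_rho=0.5, chromosome=str(c + 1), start_pos=1)
        for c in range(10)
    ]
    genotypes = simulate_genotypes(600, blocks, seed=11)
    vids = genotypes.variant_ids
    effects = EffectSpec(
        causal_variants={vids[0]: 0.6, vids[40]: -0.6, vids[80]: 0.6},
        causal_cpgs={"cg000000": 0.12, "cg000001": -0.12},
        exposure_log_ors=(0.8, 1.4),
        baseline_logit=-0.7,
        age_log_or=0.03,
    )
    cohort = simulate_phenotype(genotypes, effects, seed=12)
    meth = simulate_methylation(
        cohort, n_cpgs=50, causal_cpgs=effects.causal_cpgs, precision=40.0, seed=13,
        baseline_mean_range=(0.2, 0.8),
    )
    return PopulationSample(genotypes=genotypes, cohort=cohort, methylation=meth)
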