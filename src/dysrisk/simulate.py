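"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure the screening pipeline assumes: two
groups (chronic-disease patients and healthy controls) answering 15 binary
exposure items with group-specific prevalences taken from the reference
cohort; a latent liability that is linear-additive in the planted integer
item weights; per-subject true gut-microbiota richness anti-correlated with
that liability; and per-subject ASV count tables (taxa subsets of a fixed
pool, Dirichlet-multinomial reads) whose estimated Chao1 tracks the true
richness.

Calibration of the richness link (intercept 260, slope -8 Chao1 units per
liability point, liability noise SD 1.5 score units, richness noise SD 15
Chao1 units) places the healthy group's 25th Chao1 percentile in the low
200s, the regime in which a quartile-based dysbiosis cutoff is meaningful.
The planted truth is returned separately and never leaks into the pipeline
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    CountTable,
    ItemWeights,
    ResponseMatrix,
    SampleMetadata,
    ValidationError,
)
from .registry import ITEM_IDS, reference_prevalences

#: Default planted weights: positive on six exposure items, zero elsewhere.
DEFAULT_PLANTED_WEIGHTS: dict[str, int] = {
    "cesarean_birth": 4,
    "breastfed_lt6mo": 3,
    "frequent_ultraprocessed": 2,
    "smoking": 2,
    "recent_antibiotics": 1,
    "recent_nsaids": 1,
}

#: Phylum composition of the simulated taxon pool (fractions sum to 1).
POOL_PHYLA: dict[str, float] = {
    "Bacteroidetes": 0.28,
    "Firmicutes": 0.28,
    "Proteobacteria": 0.14,
    "Actinobacteria": 0.10,
    "Verrucomicrobia": 0.07,
    "Fusobacteria": 0.05,
    "Tenericutes": 0.03,
    "Lentisphaerae": 0.03,
    None: 0.02,  # unclassified taxa (no lineage)
}


@dataclass
class SimulationConfig:
    n_cd: int = 167
    n_hc: int = 52
    #: item -> (CD, HC) yes-probability; defaults to the reference cohort.
    item_prevalences: dict[str, tuple[float, float]] = field(
        default_factory=reference_prevalences
    )
    planted_weights: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_WEIGHTS)
    )
    liability_noise_sd: float = 1.5       # score units
    richness_intercept: float = 260.0     # Chao1 units
    richness_slope: float = 8.0           # Chao1 units lost per liability point
    richness_noise_sd: float = 15.0       # Chao1 units
    richness_floor: float = 10.0
    taxa_pool_size: int = 400
    read_depth: int = 20_000
    dirichlet_alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cd < 4 or self.n_hc < 4:
            raise ValidationError("group sizes must be >= 4")
        if self.richness_slope < 0:
            raise ValidationError("richness_slope must be >= 0")
        for item, (p_cd, p_hc) in self.item_prevalences.items():
            if not (0 <= p_cd <= 1 and 0 <= p_hc <= 1):
                raise ValidationError(f"invalid prevalence for {item!r}")


@dataclass
class PlantedTruth:
    """Per-subject ground truth, retrievable for every simulated subject."""

    sample_ids: list[str]
    liability: np.ndarray
    true_richness: np.ndarray        # integer taxa counts
    planted_weights: ItemWeights
    groups: list[str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "group": self.groups,
            "liability": self.liability,
            "true_richness": self.true_richness,
        }).set_index("sample_id")


def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int | None = 0,
) -> tuple[SampleMetadata, ResponseMatrix, pd.Series, PlantedTruth]:
    """Draw one cohort: metadata, responses, true richness, planted truth.

    Responses are independent Bernoulli draws with group-specific item
    prevalences.  Liability is L_i = sum_j w*_j x_ij + eps_i with Gaussian
    noise; true richness is S_i = max(floor, a - b L_i + eta_i), rounded to
    an integer taxa count.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    n = config.n_cd + config.n_hc
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    groups = ["CD"] * config.n_cd + ["HC"] * config.n_hc

    items = [i for i in ITEM_IDS if i in config.item_prevalences]
    extra = [i for i in config.item_prevalences if i not in ITEM_IDS]
    items += sorted(extra)
    prev = np.array([
        [config.item_prevalences[i][0 if g == "CD" else 1] for i in items]
        for g in groups
    ])
    responses = (rng.random((n, len(items))) < prev).astype(np.int8)

    w_star = np.array(
        [config.planted_weights.get(i, 0) for i in items], dtype=float
    )
    eps = rng.normal(0.0, config.liability_noise_sd, size=n)
    liability = responses @ w_star + eps
    eta = rng.normal(0.0, config.richness_noise_sd, size=n)
    richness = np.maximum(
        config.richness_floor,
        config.richness_intercept - config.richness_slope * liability + eta,
    )
    true_s = np.round(richness).astype(int)
    if (true_s > config.taxa_pool_size).any():
        raise ValidationError(
            "true richness exceeds taxa_pool_size; enlarge the pool"
        )

    meta = SampleMetadata(sample_ids, groups)
    resp = ResponseMatrix(list(sample_ids), items, responses)
    truth = PlantedTruth(
        sample_ids=list(sample_ids),
        liability=liability,
        true_richness=true_s,
        planted_weights=ItemWeights(
            {i: int(config.planted_weights.get(i, 0)) for i in items}
        ),
        groups=list(groups),
    )
    series = pd.Series(true_s.astype(float), index=sample_ids, name="true_richness")
    return meta, resp, series, truth


def _pool_taxonomy(pool_size: int, rng: np.random.Generator) -> dict[str, str]:
    """Assign pool taxa to phyla with the fixed POOL_PHYLA proportions."""
    phyla = list(POOL_PHYLA)
    counts = np.floor(np.array(list(POOL_PHYLA.values())) * pool_size).astype(int)
    counts[0] += pool_size - counts.sum()
    taxonomy: dict[str, str] = {}
    assignment = np.repeat(np.arange(len(phyla)), counts)
    for t, a in enumerate(assignment):
        phylum = phyla[a]
        if phylum is not None:
            taxonomy[f"ASV{t + 1:04d}"] = f"k__Bacteria; p__{phylum}"
    return taxonomy


def simulate_counts(
    truth: PlantedTruth,
    config: SimulationConfig | None = None,
    seed: int | None = 1,
) -> CountTable:
    """Emit an ASV count table consistent with the planted true richness.

    For each subject, S_i taxa are drawn from the shared pool, given
    Dirichlet(alpha) relative abundances, and read_depth reads are drawn
    multinomially.  Pool taxa carry a fixed phylum taxonomy (a small share
    deliberately unclassified).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    pool = config.taxa_pool_size
    taxon_ids = [f"ASV{t + 1:04d}" for t in range(pool)]
    taxonomy = _pool_taxonomy(pool, rng)
    n = len(truth.sample_ids)
    counts = np.zeros((n, pool), dtype=np.int64)
    for i, s_i in enumerate(truth.true_richness):
        if s_i > pool:
            raise ValidationError(f"true richness {s_i} exceeds pool size {pool}")
        active = rng.choice(pool, size=int(s_i), replace=False)
        probs = rng.dirichlet(np.full(int(s_i), config.dirichlet_alpha))
        counts[i, active] = rng.multinomial(config.read_depth, probs)
    return CountTable(list(truth.sample_ids), taxon_ids, counts, taxonomy)


def end_to_end_fixture(
    seed: int = 0, n: int = 60
) -> tuple[SampleMetadata, ResponseMatrix, pd.Series, PlantedTruth]:
    """Small 4-item cohort for which exhaustive search is the test oracle.

    One strongly predictive item, two weakly predictive items, one pure-noise
    item; n defaults to 60 so every optimizer test can enumerate the full
    5^4 weight grid quickly.
    """
    prevalences = {
        "cesarean_birth": (0.25, 0.55),
        "breastfed_lt6mo": (0.60, 0.55),
        "recent_antibiotics": (0.30, 0.10),
        "smoking": (0.10, 0.05),
    }
    planted = {"cesarean_birth": 4, "breastfed_lt6mo": 2, "recent_antibiotics": 1}
    n_hc = max(4, n // 4)
    config = SimulationConfig(
        n_cd=n - n_hc,
        n_hc=n_hc,
        item_prevalences=prevalences,
        planted_weights=planted,
        liability_noise_sd=1.0,
        richness_noise_sd=10.0,
    )
    return simulate_cohort(config, seed=seed)


def write_cohort(outdir, meta, responses, richness, truth) -> None:
    """Write metadata.tsv, responses.csv, richness.tsv and truth.json."""
    import json
    from pathlib import Path

    from .io import write_metadata, write_responses

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_metadata(meta, outdir / "metadata.tsv")
    write_responses(responses, outdir / "responses.csv")
    richness.rename("true_richness").to_csv(outdir / "richness.tsv", sep="\t")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "planted_weights": dict(truth.planted_weights.weights),
                "liability": truth.liability.tolist(),
                "true_richness": truth.true_richness.tolist(),
                "groups": truth.groups,
            },
            fh,
        )
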