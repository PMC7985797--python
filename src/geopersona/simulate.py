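"""Synthetic county panels, polygons, corpora and suppressed outcomes.

The generator is the forward model of the whole pipeline: a latent Gaussian
outcome per county-year driven by Big Five trait percentiles, observed
covariates, an optional omitted confounder, a county random effect and
idiosyncratic noise.  Counts are rounded and floored at zero, and any count
below the suppression threshold is released only as the censoring interval
``[0, threshold - 1]`` — mirroring the small-cell disclosure rule applied to
county mortality tables, under which roughly three quarters of US counties
have their yearly opioid-overdose counts suppressed.

Instruments are linguistic-style stand-ins: per trait, two columns built from
the county's *exogenous* trait component plus noise, so they correlate with
the trait but reach the outcome only through it (valid by construction, and
overidentified so the Sargan test has at least one degree of freedom).

Random-number draw order (one ``numpy`` Generator seeded from ``config.seed``)
is fixed per operation and documented in each docstring, so seeds remain
stable across refactors:

* ``generate_panel``: (1) county base traits, (2) trait year innovations,
  (3) confounder, (4) covariate bases, (5) covariate year noise,
  (6) instrument noise, (7) county random effects, (8) idiosyncratic errors.
* ``generate_corpus`` (independent stream, ``seed + 1``): per county-year in
  row order — tweet lengths, category indices, word indices, day-of-year
  offsets, coordinates; duplicate-injection choices last.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from geopersona.errors import ConfigurationError
from geopersona.lexicon import Lexicon, TraitWeights, TRAITS

#: default trait effects (deaths per percentile point), patterned on the
#: magnitudes a county-level analysis of this kind reports
DEFAULT_BETA = {
    "openness": 0.05,
    "conscientiousness": 0.23,
    "extraversion": 0.31,
    "agreeableness": -0.05,
    "neuroticism": 0.25,
}

DEFAULT_GAMMA = {"poverty": 1.0, "uninsured": 0.5}

#: category emitted preferentially by each trait in the bundled lexicon
TRAIT_CATEGORY = {
    "openness": "cogproc",
    "conscientiousness": "work",
    "extraversion": "social",
    "agreeableness": "posemo",
    "neuroticism": "negemo",
}

FILLER_WORDS = (
    "the and a to of in it is was for on with at by from up about into over "
    "after day time today now here just really very going get new one two "
    "see say made"
).split()


@dataclass
class SimConfig:
    """Ground-truth parameters for the synthetic study.

    ``intercept_true`` defaults to the value calibrated (once, by Monte
    Carlo at n=3000, T=3 under the default effect sizes) so that about 77%
    of county-years fall below the suppression threshold, matching the
    share of US counties whose opioid-overdose counts are suppressed.
    """

    n_counties: int = 3000
    n_years: int = 3
    start_year: int = 2014
    seed: int = 0
    suppression_threshold: int = 10
    beta_true: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    gamma_true: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    intercept_true: float = -41.6
    year_effect_step: float = 1.0
    sigma_u: float = 2.0
    sigma_e: float = 3.0
    trait_innovation_sd: float = 0.3
    confounder_strength: float = 0.0
    instrument_strength: float = 0.7
    tweets_per_county: int = 200
    words_per_tweet: int = 12
    emission_base: float = 0.05
    emission_slope: float = 0.08
    duplicate_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_e <= 0:
            raise ConfigurationError("sigma_e must be positive")
        if self.sigma_u < 0:
            raise ConfigurationError("sigma_u must be non-negative")
        if self.n_counties < 2:
            raise ConfigurationError("need at least 2 counties")
        if self.n_years < 1:
            raise ConfigurationError("need at least 1 year")
        if self.suppression_threshold < 0:
            raise ConfigurationError("suppression_threshold must be >= 0")
        if self.tweets_per_county < 1 or self.words_per_tweet < 1:
            raise ConfigurationError("corpus sizes must be positive")
        if not 0.0 <= self.instrument_strength <= 1.0:
            raise ConfigurationError("instrument_strength must be in [0, 1]")
        unknown = set(self.beta_true) - set(TRAITS)
        if unknown:
            raise ConfigurationError(f"unknown traits in beta_true: {sorted(unknown)}")

    @property
    def fips_codes(self) -> list[str]:
        return [f"{i + 1:05d}" for i in range(self.n_counties)]

    @property
    def years(self) -> list[int]:
        return [self.start_year + t for t in range(self.n_years)]


def _percentile_within(values: np.ndarray) -> np.ndarray:
    """Average-rank percentile on [0, 100]: 100 * (rank - 0.5) / n."""
    n = len(values)
    return 100.0 * (rankdata(values, method="average") - 0.5) / n


def generate_panel(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the latent county panel and the interval-censored outcomes.

    Returns ``(latent, outcomes)``.  ``latent`` has one row per county-year
    with trait percentiles, the confounder, covariates and instruments;
    ``outcomes`` has ``fips, year, lower, upper, observed_exact`` plus the
    (normally unobservable) true count in ``count_true``.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_counties, config.n_years
    traits = list(TRAITS)
    cov_names = list(config.gamma_true)

    z_base = rng.standard_normal((n, len(traits)))            # draw 1
    z_innov = rng.standard_normal((n, T, len(traits)))        # draw 2
    confounder = rng.standard_normal((n, T))                  # draw 3
    cov_base = rng.standard_normal((n, len(cov_names)))       # draw 4
    cov_noise = rng.standard_normal((n, T, len(cov_names)))   # draw 5
    inst_noise = rng.standard_normal((n, T, len(traits), 2))  # draw 6
    u = config.sigma_u * rng.standard_normal(n)               # draw 7
    e = config.sigma_e * rng.standard_normal((n, T))          # draw 8

    # trait latent: persistent county component + small yearly innovation
    # (traits are stable but not frozen; the within-estimator needs variation)
    # + confounder loading
    lam = config.confounder_strength
    trait_latent = (
        z_base[:, None, :]
        + config.trait_innovation_sd * z_innov
        + lam * confounder[:, :, None]
    )

    # percentile-rank traits within each year (cross-county comparability)
    pct = np.empty_like(trait_latent)
    for t in range(T):
        for j in range(len(traits)):
            pct[:, t, j] = _percentile_within(trait_latent[:, t, j])

    covariates = cov_base[:, None, :] + 0.3 * cov_noise

    # instruments built from the exogenous trait component only
    s = config.instrument_strength
    z_std = (z_base - z_base.mean(axis=0)) / z_base.std(axis=0)
    instruments = s * z_std[:, None, :, None] + np.sqrt(1.0 - s**2) * inst_noise

    beta_vec = np.array([config.beta_true.get(t, 0.0) for t in traits])
    gamma_vec = np.array([config.gamma_true[c] for c in cov_names])
    year_fx = config.year_effect_step * np.arange(T)

    y_star = (
        config.intercept_true
        + pct @ beta_vec
        + covariates @ gamma_vec
        + lam * confounder
        + year_fx[None, :]
        + u[:, None]
        + e
    )
    count = np.rint(np.clip(y_star, 0.0, None))
    suppressed = count < config.suppression_threshold

    fips = np.repeat(config.fips_codes, T)
    year = np.tile(config.years, n)
    latent = pd.DataFrame({"fips": fips, "year": year})
    for j, t in enumerate(traits):
        latent[t] = pct[:, :, j].ravel()
    latent["confounder"] = confounder.ravel()
    for j, c in enumerate(cov_names):
        latent[c] = covariates[:, :, j].ravel()
    for j, t in enumerate(traits):
        for k in range(2):
            latent[f"z_{t}_{k + 1}"] = instruments[:, :, j, k].ravel()

    outcomes = pd.DataFrame(
        {
            "fips": fips,
            "year": year,
            "lower": np.where(suppressed, 0.0, count).ravel(),
            "upper": np.where(
                suppressed, float(config.suppression_threshold - 1), count
            ).ravel(),
            "observed_exact": ~suppressed.ravel(),
            "count_true": count.ravel(),
        }
    )
    if config.suppression_threshold == 0:
        # nothing can fall below a zero threshold
        outcomes["lower"] = outcomes["upper"] = count.ravel()
        outcomes["observed_exact"] = True
    return latent, outcomes


def generate_polygons(config: SimConfig) -> dict:
    """A GeoJSON FeatureCollection of axis-aligned unit squares, one per county.

    Counties tile an m x m grid (m = ceil(sqrt(n_counties))), row-major, with
    cell ``k`` spanning lon [col, col+1] and lat [row, row+1].  Deterministic;
    uses no random numbers.
    """
    m = int(np.ceil(np.sqrt(config.n_counties)))
    features = []
    for k, fips in enumerate(config.fips_codes):
        col, row = k % m, k // m
        ring = [
            [col, row],
            [col + 1, row],
            [col + 1, row + 1],
            [col, row + 1],
            [col, row],
        ]
        features.append(
            {
                "type": "Feature",
                "properties": {"fips": fips},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def generate_corpus(
    latent: pd.DataFrame,
    lexicon: Lexicon,
    config: SimConfig,
    trait_category: Mapping[str, str] | None = None,
) -> list[dict]:
    """Emit geo-tagged tweets whose category usage is affine in trait percentiles.

    Each token is drawn from a mixture: category ``c`` (tied to one trait) with
    probability ``emission_base + emission_slope * (pct/100 - 0.5)``, clipped
    at a small floor, else a filler word.  Category words are the lexicon's
    patterns with wildcard stars stripped (a stripped prefix still matches its
    own wildcard).  Coordinates are uniform inside the county's grid cell;
    author ids are globally unique unless ``duplicate_fraction > 0``.
    """
    if trait_category is None:
        trait_category = TRAIT_CATEGORY
    if not lexicon.categories:
        raise ConfigurationError("empty lexicon")
    for cat in trait_category.values():
        if cat not in lexicon.categories:
            raise ConfigurationError(f"category {cat!r} not in lexicon")

    rng = np.random.default_rng(config.seed + 1)
    m = int(np.ceil(np.sqrt(config.n_counties)))
    cell_of = {f: (k % m, k // m) for k, f in enumerate(config.fips_codes)}
    traits = [t for t in TRAITS if t in trait_category]
    cat_words = [
        [p[:-1] if p.endswith("*") else p for p in lexicon.categories[trait_category[t]]]
        for t in traits
    ]
    n_cat = len(traits)

    records: list[dict] = []
    for row_idx, row in enumerate(latent.itertuples(index=False)):
        pcts = np.array([getattr(row, t) for t in traits])
        probs = np.clip(
            config.emission_base + config.emission_slope * (pcts / 100.0 - 0.5),
            1e-4,
            None,
        )
        if probs.sum() >= 1.0:
            raise ConfigurationError("emission probabilities exceed 1; lower base/slope")
        p_full = np.append(probs, 1.0 - probs.sum())
        # tweet lengths vary around words_per_tweet (floor 3 survives filtering)
        lengths = 3 + rng.poisson(
            max(config.words_per_tweet - 3, 0), size=config.tweets_per_county
        )
        bounds = np.r_[0, np.cumsum(lengths)]
        n_tok = int(bounds[-1])
        cats = rng.choice(n_cat + 1, size=n_tok, p=p_full)
        word_draw = rng.random(n_tok)
        days = rng.integers(0, 365, size=config.tweets_per_county)
        coords = rng.random((config.tweets_per_county, 2))
        col, cell_row = cell_of[row.fips]
        tokens = np.empty(n_tok, dtype=object)
        for c in range(n_cat):
            mask = cats == c
            words = cat_words[c]
            tokens[mask] = [words[int(w * len(words))] for w in word_draw[mask]]
        mask = cats == n_cat
        tokens[mask] = [
            FILLER_WORDS[int(w * len(FILLER_WORDS))] for w in word_draw[mask]
        ]
        base = _dt.datetime(int(row.year), 1, 1, tzinfo=_dt.timezone.utc)
        for j in range(config.tweets_per_county):
            text = " ".join(tokens[bounds[j] : bounds[j + 1]])
            ts = base + _dt.timedelta(days=int(days[j]), minutes=j)
            records.append(
                {
                    "author": f"u{row_idx}_{j}",
                    "ts": ts.isoformat(),
                    "lat": cell_row + float(coords[j, 1]),
                    "lon": col + float(coords[j, 0]),
                    "text": text,
                }
            )
    if config.duplicate_fraction > 0:
        n_dup = int(config.duplicate_fraction * len(records))
        picks = rng.choice(len(records), size=n_dup, replace=False)
        for i in picks:
            records.append(dict(records[int(i)]))
    return records


def generate_facets(
    latent: pd.DataFrame,
    config: SimConfig,
    n_alpha: int = 10,
    n_beta: int = 6,
    loading: float = 0.75,
) -> pd.DataFrame:
    """Facet matrices with a planted two-block correlation structure.

    Alpha (stability) facets load on a latent built from conscientiousness,
    agreeableness and reversed neuroticism percentiles; beta (plasticity)
    facets on extraversion and openness.  Each facet is
    ``loading * block latent + sqrt(1 - loading^2) * unique noise`` so the
    within-block correlation is ``loading**2``.  Uses an independent RNG
    stream (``seed + 2``); draw order: alpha noise then beta noise.
    """
    rng = np.random.default_rng(config.seed + 2)
    z = lambda v: (v - v.mean()) / v.std()  # noqa: E731
    alpha_latent = z(
        z(latent["conscientiousness"])
        + z(latent["agreeableness"])
        - z(latent["neuroticism"])
    ).to_numpy()
    beta_latent = z(z(latent["extraversion"]) + z(latent["openness"])).to_numpy()
    n = len(latent)
    resid = np.sqrt(1.0 - loading**2)
    out = latent[["fips", "year"]].copy()
    noise_a = rng.standard_normal((n, n_alpha))
    noise_b = rng.standard_normal((n, n_beta))
    for j in range(n_alpha):
        out[f"alpha_f{j + 1}"] = loading * alpha_latent + resid * noise_a[:, j]
    for j in range(n_beta):
        out[f"beta_f{j + 1}"] = loading * beta_latent + resid * noise_b[:, j]
    return out


# ---------------------------------------------------------------------------
# writers

def write_tweets_jsonl(records: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r) + "\n")


def write_polygons_geojson(collection: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(collection))


def write_panel_csv(
    latent: pd.DataFrame, outcomes: pd.DataFrame, path: str | Path
) -> None:
    """Merged CSV: fips,year,lower,upper,observed_exact,<covariates>,<instruments>."""
    merged = outcomes.drop(columns=["count_true"]).merge(
        latent.drop(columns=list(TRAITS) + ["confounder"]), on=["fips", "year"]
    )
    merged.to_csv(path, index=False)


def write_truth(config: SimConfig, path: str | Path) -> None:
    """Flat key-value file of the generator's ground-truth parameters."""
    flat: dict[str, object] = {}
    for key, val in asdict(config).items():
        if isinstance(val, dict):
            for k, v in val.items():
                flat[f"{key}.{k}"] = v
        else:
            flat[key] = val
    Path(path).write_text(
        "\n".join(f"{k}={v}" for k, v in flat.items()) + "\n"
    )
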