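"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes —
per-ingredient compound property distributions, sparse bipartite
compound-target edges, gene-set catalogs with planted enriched terms, and
balanced 2^k factorial plates with specified effects and Gaussian noise —
so every stage is testable without any database download. Each generator
is a pure function of its configuration, seed included: the same config
yields bit-identical output.

Default scales follow the study this pipeline was built around: a 572-
compound six-ingredient library, a 102-compound / 200-target network with
mean compound degree ~10, a 9841-gene universe queried with 146 genes, and
a three-compound two-level OD450 plate with 5 replicates per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .catalog import CompoundTable
from .enrichment import GeneSetCatalog
from .errors import ConfigError

__all__ = [
    "LibrarySpec",
    "NetworkSpec",
    "CatalogSpec",
    "FactorialSpec",
    "SyntheticConfig",
    "simulate_compound_library",
    "simulate_ct_edges",
    "simulate_factorial",
    "simulate_geneset_catalog",
]

#: per-ingredient compound counts of the reference six-herb library
DEFAULT_INGREDIENT_COUNTS = {"PR": 120, "RO": 93, "RG": 77, "PS": 56, "PN": 120, "AT": 106}

#: per-ingredient molecular-weight location (Da), roughly herb-specific
DEFAULT_MW_LOCATION = {"PR": 322.0, "RO": 443.0, "RG": 362.0, "PS": 350.0, "PN": 368.0, "AT": 227.0}


@dataclass
class LibrarySpec:
    """Compound-library generator parameters.

    MW is log-normal around a per-ingredient location; MLOGP, OB and DL
    are normal (clipped to their valid ranges); donor/acceptor counts are
    Poisson. ``missing_fraction`` is the probability that a compound's OB
    and DL are both unrecorded.
    """

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_INGREDIENT_COUNTS))
    mw_location: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MW_LOCATION))
    mw_sigma: float = 0.45
    mlogp: tuple[float, float] = (2.3, 1.6)
    nhdon_rate: float = 3.2
    nhacc_rate: float = 5.6
    ob: tuple[float, float] = (30.0, 14.0)
    dl: tuple[float, float] = (0.28, 0.2)
    missing_fraction: float = 0.03

    def validate(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ConfigError("ingredient counts must be >= 0")
        if self.mw_sigma < 0 or self.mlogp[1] < 0 or self.ob[1] < 0 or self.dl[1] < 0:
            raise ConfigError("scale parameters must be >= 0")
        if min(self.nhdon_rate, self.nhacc_rate) < 0:
            raise ConfigError("Poisson rates must be >= 0")
        if not 0 <= self.missing_fraction <= 1:
            raise ConfigError("missing_fraction must lie in [0, 1]")


@dataclass
class NetworkSpec:
    """Bipartite compound-target edge generator parameters."""

    n_compounds: int = 102
    n_targets: int = 200
    mean_degree: float = 10.0

    def validate(self) -> None:
        if min(self.n_compounds, self.n_targets) < 0:
            raise ConfigError("node counts must be >= 0")
        if self.mean_degree < 0:
            raise ConfigError("mean_degree must be >= 0")
        if self.n_targets and self.mean_degree > self.n_targets:
            raise ConfigError(
                f"mean degree {self.mean_degree} exceeds target count {self.n_targets}"
            )


@dataclass
class CatalogSpec:
    """Gene-set catalog generator parameters with planted enriched terms."""

    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 60)
    universe_size: int = 9841
    n_planted: int = 5
    overlap_fraction: float = 0.8
    query_size: int = 146

    def validate(self) -> None:
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi:
            raise ConfigError("term_size_range must satisfy 1 <= lo <= hi")
        if hi > self.universe_size:
            raise ConfigError("largest term size exceeds the universe")
        if not 0 <= self.overlap_fraction <= 1:
            raise ConfigError("overlap_fraction must lie in [0, 1]")
        if not 0 <= self.n_planted <= self.n_terms:
            raise ConfigError("n_planted must lie in [0, n_terms]")
        if not 0 < self.query_size <= self.universe_size:
            raise ConfigError("query_size must lie in (0, universe_size]")


@dataclass
class FactorialSpec:
    """Balanced 2^k factorial plate generator parameters.

    Effects are on the response scale per coded unit (low -> high change);
    a cell's mean is baseline + sum(coded * main/2) + sum(product of coded
    * interaction/2). Defaults emulate a three-compound OD450 plate.
    """

    factors: tuple[str, ...] = ("Taurine", "Paeonol", "Geniposide")
    n: int = 5
    baseline: float = 1.4295
    main_effects: tuple[float, ...] = (-0.1705, -0.076, -0.056)
    interaction_effects: dict[tuple[str, ...], float] = field(
        default_factory=lambda: {
            ("Taurine", "Paeonol"): -0.0665,
            ("Taurine", "Geniposide"): -0.0575,
            ("Paeonol", "Geniposide"): 0.052,
            ("Taurine", "Paeonol", "Geniposide"): 0.0375,
        }
    )
    noise_sd: float = 0.065

    def validate(self) -> None:
        if len(self.factors) < 2:
            raise ConfigError("need k >= 2 factors")
        if len(self.main_effects) != len(self.factors):
            raise ConfigError("one main effect per factor required")
        if self.n < 2:
            raise ConfigError("n must be >= 2 replicates per cell")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for term in self.interaction_effects:
            if not set(term) <= set(self.factors):
                raise ConfigError(f"interaction term {term} names unknown factors")


@dataclass
class SyntheticConfig:
    """Seeded configuration bundling all generator specs."""

    seed: int = 0
    library: LibrarySpec = field(default_factory=LibrarySpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    catalog: CatalogSpec = field(default_factory=CatalogSpec)
    factorial: FactorialSpec = field(default_factory=FactorialSpec)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "SyntheticConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(
            seed=doc.get("seed", 0),
            library=LibrarySpec(**doc.get("library", {})),
            network=NetworkSpec(**doc.get("network", {})),
            catalog=CatalogSpec(**doc.get("catalog", {})),
            factorial=_factorial_from_dict(doc.get("factorial", {})),
        )
        if seed is not None:
            cfg.seed = seed
        return cfg


def _factorial_from_dict(doc: Mapping) -> FactorialSpec:
    doc = dict(doc)
    if "factors" in doc:
        doc["factors"] = tuple(doc["factors"])
    if "main_effects" in doc:
        doc["main_effects"] = tuple(doc["main_effects"])
    if "interaction_effects" in doc:
        doc["interaction_effects"] = {
            tuple(k.split(":")): float(v) for k, v in doc["interaction_effects"].items()
        }
    return FactorialSpec(**doc)


def simulate_compound_library(config: SyntheticConfig) -> CompoundTable:
    """Draw a per-ingredient compound library matching the spec'd counts."""
    spec = config.library
    spec.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for ing in sorted(spec.counts):
        count = spec.counts[ing]
        if count == 0:
            continue
        mw_loc = spec.mw_location.get(ing, 350.0)
        mw = np.exp(rng.normal(np.log(mw_loc), spec.mw_sigma, count))
        mlogp = rng.normal(*spec.mlogp, size=count)
        nhdon = rng.poisson(spec.nhdon_rate, count)
        nhacc = rng.poisson(spec.nhacc_rate, count)
        ob = np.clip(rng.normal(*spec.ob, size=count), 0.0, None)
        dl = np.clip(rng.normal(*spec.dl, size=count), 0.0, 1.0)
        miss = rng.random(count) < spec.missing_fraction
        ob[miss] = np.nan
        dl[miss] = np.nan
        for i in range(count):
            rows.append(
                {
                    "id": f"{ing}{i + 1}",
                    "name": f"{ing} compound {i + 1}",
                    "ingredient": ing,
                    "mw": round(float(mw[i]), 2),
                    "mlogp": round(float(mlogp[i]), 2),
                    "nhdon": int(nhdon[i]),
                    "nhacc": int(nhacc[i]),
                    "ob": round(float(ob[i]), 2) if np.isfinite(ob[i]) else np.nan,
                    "dl": round(float(dl[i]), 2) if np.isfinite(dl[i]) else np.nan,
                    "evidence": False,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["id", "name", "ingredient", "mw", "mlogp", "nhdon", "nhacc", "ob", "dl", "evidence"],
    )
    return CompoundTable(df, provenance=f"simulate_compound_library(seed={config.seed})")


def simulate_ct_edges(config: SyntheticConfig) -> list[tuple[str, str]]:
    """Draw sparse bipartite compound-target edges.

    Each compound-target pair is an independent Bernoulli draw with
    probability mean_degree / n_targets; afterwards every isolated node
    receives one uniform edge so the built network realizes all declared
    compounds and targets. A mean degree of 0 yields no edges at all.
    """
    spec = config.network
    spec.validate()
    rng = np.random.default_rng(config.seed)
    compounds = [f"C{i + 1:03d}" for i in range(spec.n_compounds)]
    targets = [f"TGT{i + 1:04d}" for i in range(spec.n_targets)]
    if spec.mean_degree == 0 or not compounds or not targets:
        return []
    p = spec.mean_degree / spec.n_targets
    adj = rng.random((spec.n_compounds, spec.n_targets)) < p
    # patch isolated nodes so the realized network covers every declared node
    for i in np.flatnonzero(~adj.any(axis=1)):
        adj[i, rng.integers(spec.n_targets)] = True
    for j in np.flatnonzero(~adj.any(axis=0)):
        adj[rng.integers(spec.n_compounds), j] = True
    ci, ti = np.nonzero(adj)
    return [(compounds[i], targets[j]) for i, j in zip(ci, ti)]


def simulate_factorial(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a balanced long-format 2^k plate with the spec'd effects.

    Response per replicate: baseline + sum of coded*(main effect)/2 +
    sum of coded-product*(interaction effect)/2 + Gaussian(0, noise_sd).
    """
    from .factorial import FactorialDesign  # local import avoids a cycle

    spec = config.factorial
    spec.validate()
    rng = np.random.default_rng(config.seed)
    design = FactorialDesign(spec.factors)
    idx = {f: i for i, f in enumerate(spec.factors)}
    inter = {tuple(sorted(t)): v for t, v in spec.interaction_effects.items()}
    rows = []
    for cell in design.cells():
        mu = spec.baseline
        mu += sum(cell[i] * e / 2 for i, e in enumerate(spec.main_effects))
        for term, eff in inter.items():
            mu += np.prod([cell[idx[f]] for f in term]) * eff / 2
        noise = rng.normal(0.0, spec.noise_sd, spec.n) if spec.noise_sd > 0 else np.zeros(spec.n)
        for r in range(spec.n):
            rows.append({**dict(zip(spec.factors, cell)), "replicate": r + 1,
                         "response": mu + noise[r]})
    return pd.DataFrame(rows)


def simulate_geneset_catalog(
    config: SyntheticConfig,
) -> tuple[GeneSetCatalog, list[str], list[str]]:
    """Draw a catalog with planted enriched terms plus a matching query.

    Planted terms take round(overlap_fraction * term size) of their genes
    from the query (capped at the query size) and the rest from the
    background; background terms are uniform draws from the universe.
    Returns (catalog, query genes, planted term names).
    """
    spec = config.catalog
    spec.validate()
    rng = np.random.default_rng(config.seed)
    universe = np.array([f"G{i + 1:05d}" for i in range(spec.universe_size)])
    query = rng.choice(universe, size=spec.query_size, replace=False)
    query_set = set(query)
    background = np.array(sorted(set(universe) - query_set))
    lo, hi = spec.term_size_range
    terms: dict[str, frozenset[str]] = {}
    planted: list[str] = []
    for t in range(spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        if t < spec.n_planted:
            name = f"PLANTED{t + 1:02d}"
            n_hit = min(int(round(spec.overlap_fraction * size)), len(query))
            hits = rng.choice(query, size=n_hit, replace=False)
            rest = rng.choice(background, size=size - n_hit, replace=False)
            genes = np.concatenate([hits, rest])
            planted.append(name)
        else:
            name = f"TERM{t + 1:03d}"
            genes = rng.choice(universe, size=size, replace=False)
        terms[name] = frozenset(genes)
    catalog = GeneSetCatalog(terms, spec.universe_size)
    return catalog, list(query), planted
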