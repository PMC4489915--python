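"""Synthetic two-genotype, seven-stage fruit transcriptome generator.

Emulates the statistical structure the screen assumes: thousands of
genes whose log2 expression follows one of ~20 canonical temporal
archetypes (monotone rise/fall, peak, valley, high-low-high, flat-high,
late induction, ...) plus multiplicative log-normal noise; a catalog of
transcription factors and three biosynthetic pathways (ascorbate,
carotenoid, flavonoid structural genes); planted signed TF->target
co-expression links whose strength is controlled by ``effect_size`` and
``noise_sd``; and metabolites that accumulate as noisy integrals
(cumulative stage-sums) of their pathway's mean expression.  The second
genotype reuses the first genotype's truth but lags ripening-linked
archetypes by one stage, mimicking an early- vs late-maturing cultivar
pair.  All randomness flows from a single seed; identical seeds give
bit-identical output.

A planted link sets the target's log2 profile to an affine image of its
regulator's realized log2 profile (slope = sign * effect_size) plus
independent N(0, noise_sd) noise per stage, so with zero noise the pair
correlates at exactly +/-1 on the log scale.  Each linked target has a
single regulator (two conflicting parents cannot both be reproduced
exactly), so per-pathway link counts may not exceed the pathway size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coexpression_screen import CorrelationRecord
from .data_model import (
    DEFAULT_STAGES,
    ExpressionMatrix,
    GeneCatalog,
    MetaboliteSeries,
    StageAxis,
)

__all__ = [
    "SimConfig",
    "PlantedLink",
    "SyntheticTruth",
    "SimResult",
    "ArchetypeSet",
    "RecoveryMetrics",
    "generate_archetypes",
    "simulate_experiment",
    "simulate_null_profiles",
    "recovery_metrics",
]

_TF_FAMILIES = ("MYB", "NAC", "bHLH", "Dof", "AUX/IAA", "CCCH-ZF", "MADS-box",
                "WRKY", "ERF", "LIM", "SBP-box", "HSF")

_PATHWAY_PREFIX = {"ascorbate": "ASC", "carotenoid": "CAR", "flavonoid": "FLA"}

#: Metabolites per pathway (ascorbate forms reported separately).
PATHWAY_METABOLITES: dict[str, tuple[str, ...]] = {
    "ascorbate": ("total-AsA", "AsA", "DHA"),
    "carotenoid": ("lycopene", "beta-carotene", "phytoene", "lutein"),
    "flavonoid": ("naringenin-chalcone", "rutin", "chlorogenic-acid"),
}

_PATHWAY_UNITS = {"ascorbate": "mg g-1", "carotenoid": "ug g-1",
                  "flavonoid": "mg g-1"}


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: 2 genotypes x 7 stages, 823 TFs, pathway
    sizes 46/18/14, 20 temporal archetypes, 50 planted links."""

    stages: tuple[int, ...] = DEFAULT_STAGES
    n_genotypes: int = 2
    genotype_ids: tuple[str, ...] = ("AC", "HG6-61")
    n_tfs: int = 823
    pathway_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"ascorbate": 46, "carotenoid": 18,
                                 "flavonoid": 14})
    n_background_genes: int = 25000
    n_archetypes: int = 20
    n_links: Mapping[str, int] = field(
        default_factory=lambda: {"ascorbate": 30, "carotenoid": 12,
                                 "flavonoid": 8})
    effect_size: float = 1.0
    noise_sd: float = 0.1
    metabolite_noise_sd: float = 0.05
    count_model: str = "none"          # "none" | "negative-binomial"
    dispersion: float = 0.1
    library_size: int = 5_000_000
    stage_lag: int = 1                 # genotype-2 lag of ripening archetypes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 1 or self.n_genotypes > len(self.genotype_ids):
            raise ValueError("n_genotypes must fit genotype_ids")
        if self.n_tfs < 1 or self.n_background_genes < 0:
            raise ValueError("gene counts must be positive")
        if self.n_archetypes < 2:
            raise ValueError("need at least 2 archetypes")
        if self.noise_sd < 0 or self.metabolite_noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.count_model not in ("none", "negative-binomial"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        for name, n in self.n_links.items():
            size = self.pathway_sizes.get(name, 0)
            if n > self.n_tfs * size:
                raise ValueError(
                    f"{name}: n_links {n} exceeds n_tfs x pathway size")
            if n > size:
                raise ValueError(
                    f"{name}: n_links {n} exceeds pathway size {size} "
                    "(one regulator per target)")

    @property
    def axis(self) -> StageAxis:
        return StageAxis(self.stages)


@dataclass(frozen=True)
class PlantedLink:
    tf_id: str
    target_id: str
    sign: int                  # +1 or -1
    effect_size: float

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")


@dataclass
class SyntheticTruth:
    links: list[PlantedLink]
    archetype_of: dict[str, int]
    noise_sd: float
    library_sizes: dict[str, list[int]]
    seed: int
    config: SimConfig

    def link_set(self) -> set[tuple[str, str]]:
        return {(l.tf_id, l.target_id) for l in self.links}

    def sign_of(self) -> dict[tuple[str, str], int]:
        return {(l.tf_id, l.target_id): l.sign for l in self.links}


@dataclass
class SimResult:
    matrices: dict[str, ExpressionMatrix]
    catalog: GeneCatalog
    metabolites: list[MetaboliteSeries]
    truth: SyntheticTruth


@dataclass
class ArchetypeSet:
    names: list[str]
    shapes: np.ndarray             # k x n_stages, unit-scaled (max = 1)
    ripening: np.ndarray           # bool mask: induced toward ripening

    def __len__(self) -> int:
        return len(self.names)


def _sigmoid(u: np.ndarray, c: float, s: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-s * (u - c)))


def _gauss(u: np.ndarray, c: float, w: float) -> np.ndarray:
    return np.exp(-((u - c) ** 2) / (2.0 * w * w))


def _base_shapes(u: np.ndarray) -> list[tuple[str, np.ndarray, bool]]:
    """Canonical family first (name, values, ripening-linked flag)."""
    return [
        ("increasing", u.copy(), True),
        ("decreasing", 1.0 - u, False),
        ("peak", _gauss(u, 0.5, 0.16), False),
        ("valley", 1.0 - 0.7 * _gauss(u, 0.5, 0.32), False),
        ("high-low-high", 1.0 - _gauss(u, 0.45, 0.14), False),
        # near-flat but not affine-equivalent to any monotone shape
        ("flat-high", 1.0 - 0.06 * (u - 0.35) ** 2, False),
        ("late-induction", _sigmoid(u, 0.72, 14.0), True),
        ("early-shutdown", 1.0 - _sigmoid(u, 0.3, 14.0), False),
        ("mid-induction", _sigmoid(u, 0.5, 9.0), True),
        ("peak-early", _gauss(u, 0.25, 0.13), False),
        ("peak-late", _gauss(u, 0.78, 0.13), True),
        ("valley-early", 1.0 - _gauss(u, 0.25, 0.13), False),
        ("valley-late", 1.0 - _gauss(u, 0.75, 0.13), False),
        ("ramp-then-flat", np.clip(2.0 * u, 0.0, 1.0) * 0.98 + 0.02 * u, True),
        ("flat-then-decay", 1.0 - np.clip(2.0 * u - 1.0, 0.0, 1.0), False),
        ("double-peak", _gauss(u, 0.22, 0.09) + _gauss(u, 0.75, 0.09), False),
        ("late-spike", _gauss(u, 0.93, 0.09), True),
        ("early-spike", _gauss(u, 0.07, 0.09), False),
        ("slow-rise-fall", np.sin(np.pi * u) ** 0.5, False),
        ("late-shutdown", 1.0 - _sigmoid(u, 0.8, 16.0), False),
    ]


def _variant_shapes(u: np.ndarray) -> Iterable[tuple[str, np.ndarray, bool]]:
    """Endless deterministic stream of parameterized variants for k > 20."""
    golden = 0.6180339887498949
    i = 0
    while True:
        c = 0.1 + 0.8 * ((0.17 + i * golden) % 1.0)
        w = 0.08 + 0.1 * ((0.41 + i * golden) % 1.0)
        kind = i % 3
        if kind == 0:
            yield (f"peak-c{c:.2f}", _gauss(u, c, w), c > 0.6)
        elif kind == 1:
            yield (f"valley-c{c:.2f}", 1.0 - _gauss(u, c, w), False)
        else:
            yield (f"sigmoid-c{c:.2f}", _sigmoid(u, c, 6.0 + 60.0 * w), c > 0.5)
        i += 1


def _unit_scale(v: np.ndarray) -> np.ndarray:
    v = v - min(0.0, float(v.min()))
    peak = float(v.max())
    return v / peak if peak > 0 else v


def generate_archetypes(k: int, axis: StageAxis = StageAxis()) -> ArchetypeSet:
    """``k`` distinct canonical temporal shapes over ``axis``.

    The first shapes cover the canonical families (monotone rise/fall,
    peak, valley, high-low-high, flat-high, late induction, ...); beyond
    the base family, parameterized variants are generated.  Any candidate
    correlating at |r| >= 0.95 with an accepted shape is skipped, so
    distinct archetypes are never near-duplicates.
    """
    if k < 2:
        raise ValueError("need k >= 2 archetypes")
    n = len(axis)
    u = (np.asarray(axis.stages, dtype=float) - axis.stages[0]) / (
        axis.stages[-1] - axis.stages[0])
    names: list[str] = []
    shapes: list[np.ndarray] = []
    flags: list[bool] = []

    def accept(name: str, values: np.ndarray, flag: bool) -> None:
        values = _unit_scale(values)
        for prev in shapes:
            a = values - values.mean()
            b = prev - prev.mean()
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            # signed check: mirrored shapes (r = -1) are distinct patterns
            if denom > 0 and float(a @ b) / denom >= 0.95:
                return
        names.append(name)
        shapes.append(values)
        flags.append(flag)

    for name, values, flag in _base_shapes(u):
        if len(names) == k:
            break
        accept(name, values, flag)
    variants = _variant_shapes(u)
    attempts = 0
    while len(names) < k:
        accept(*next(variants))
        attempts += 1
        if attempts > 10000:
            raise ValueError(f"could not construct {k} distinct archetypes")
    return ArchetypeSet(names=names, shapes=np.vstack(shapes),
                        ripening=np.asarray(flags, dtype=bool))


def _lagged(shapes: np.ndarray, ripening: np.ndarray, lag: int) -> np.ndarray:
    """Shift ripening-linked shapes ``lag`` stages later (edge-held)."""
    if lag <= 0:
        return shapes
    out = shapes.copy()
    idx = np.concatenate([np.zeros(lag, dtype=int),
                          np.arange(shapes.shape[1] - lag)])
    out[ripening] = shapes[ripening][:, idx]
    return out


def _make_ids(cfg: SimConfig) -> tuple[list[str], dict[str, list[str]], list[str]]:
    tf_ids = [f"TF{i + 1:04d}" for i in range(cfg.n_tfs)]
    pathways = {
        name: [f"{_PATHWAY_PREFIX.get(name, name[:3].upper())}{i + 1:03d}"
               for i in range(size)]
        for name, size in cfg.pathway_sizes.items()
    }
    background = [f"BG{i + 1:05d}" for i in range(cfg.n_background_genes)]
    return tf_ids, pathways, background


def simulate_experiment(cfg: SimConfig = SimConfig()) -> SimResult:
    """Generate expression matrices, catalog, metabolites and truth.

    Deterministic for a fixed ``cfg.seed``; see the module docstring for
    the generative model.
    """
    rng = np.random.default_rng(cfg.seed)
    axis = cfg.axis
    n = len(axis)
    arch = generate_archetypes(cfg.n_archetypes, axis)
    tf_ids, pathways, background = _make_ids(cfg)
    structural = [g for genes in pathways.values() for g in genes]
    all_ids = tf_ids + structural + background

    # per-gene parameters, shared across genotypes
    arch_of = {g: int(a) for g, a in
               zip(all_ids, rng.integers(0, len(arch), size=len(all_ids)))}
    base_draw = rng.uniform(2.5, 7.5, size=len(all_ids))
    # background genes span low expression too, so the RPKM floor removes
    # a realistic fraction; TFs and structural genes stay in the
    # expressed range the screen operates on
    n_fg = len(tf_ids) + len(structural)
    base_draw[n_fg:] = (base_draw[n_fg:] - 2.5) * 1.8 - 1.5
    baseline = dict(zip(all_ids, base_draw))
    amplitude = dict(zip(all_ids, rng.uniform(2.0, 4.0, size=len(all_ids))))

    # planted regulator -> target links (one regulator per target)
    links: list[PlantedLink] = []
    for name in sorted(cfg.n_links):
        k_links = cfg.n_links[name]
        if k_links == 0:
            continue
        targets = rng.choice(pathways[name], size=k_links, replace=False)
        regulators = rng.choice(tf_ids, size=k_links, replace=True)
        signs = rng.choice([1, -1], size=k_links)
        for tf, tgt, s in zip(regulators, targets, signs):
            links.append(PlantedLink(str(tf), str(tgt), int(s),
                                     cfg.effect_size))
    linked_by_target = {l.target_id: l for l in links}

    gene_lengths = dict(zip(all_ids, rng.uniform(500, 5000, size=len(all_ids))))
    matrices: dict[str, ExpressionMatrix] = {}
    library_sizes: dict[str, list[int]] = {}

    for g_idx in range(cfg.n_genotypes):
        geno = cfg.genotype_ids[g_idx]
        shapes = (arch.shapes if g_idx == 0
                  else _lagged(arch.shapes, arch.ripening, cfg.stage_lag))
        centered = shapes - shapes.mean(axis=1, keepdims=True)
        log2x = np.empty((len(all_ids), n))
        # regulators and free genes first
        for i, gene in enumerate(all_ids):
            if gene in linked_by_target:
                continue
            log2x[i] = (baseline[gene]
                        + amplitude[gene] * centered[arch_of[gene]]
                        + rng.normal(0.0, cfg.noise_sd, size=n))
        idx_of = {gene: i for i, gene in enumerate(all_ids)}
        # linked targets follow their regulator's realized profile
        for link in links:
            tf_profile = log2x[idx_of[link.tf_id]]
            i = idx_of[link.target_id]
            log2x[i] = (baseline[link.target_id]
                        + link.effect_size * link.sign
                        * (tf_profile - tf_profile.mean())
                        + rng.normal(0.0, cfg.noise_sd, size=n))
        rpkm = np.power(2.0, log2x)
        if cfg.count_model == "negative-binomial":
            lengths = np.array([gene_lengths[g] for g in all_ids])
            mu = rpkm * lengths[:, None] * cfg.library_size / 1e9
            if cfg.dispersion > 0:
                r_nb = 1.0 / cfg.dispersion
                p_nb = r_nb / (r_nb + mu)
                counts = rng.negative_binomial(r_nb, p_nb)
            else:
                counts = rng.poisson(mu)
            rpkm = 1e9 * counts / (cfg.library_size * lengths[:, None])
            library_sizes[geno] = [cfg.library_size] * n
        else:
            library_sizes[geno] = [cfg.library_size] * n
        data = pd.DataFrame(rpkm, index=all_ids, columns=list(axis.stages))
        matrices[geno] = ExpressionMatrix(geno, axis, data)

    catalog = GeneCatalog(
        pathways={name: list(genes) for name, genes in pathways.items()},
        tf_ids=list(tf_ids),
        tf_family={tf: _TF_FAMILIES[i % len(_TF_FAMILIES)]
                   for i, tf in enumerate(tf_ids)},
    )

    # metabolites: noisy integrals of pathway mean expression
    metabolites: list[MetaboliteSeries] = []
    for name in sorted(pathways):
        mets = PATHWAY_METABOLITES.get(name, (f"{name}-product",))
        for geno in list(matrices):
            path_mean = matrices[geno].data.loc[pathways[name]].mean(axis=0)
            accumulated = np.cumsum(path_mean.to_numpy())
            for m_idx, met_id in enumerate(mets):
                rate = 10.0 ** (-(m_idx + 1))
                noise = np.exp(rng.normal(0.0, cfg.metabolite_noise_sd, size=n))
                metabolites.append(MetaboliteSeries(
                    metabolite_id=met_id, genotype_id=geno, axis=axis,
                    values=rate * accumulated * noise,
                    units=_PATHWAY_UNITS.get(name, "a.u.")))

    truth = SyntheticTruth(links=links, archetype_of=arch_of,
                           noise_sd=cfg.noise_sd,
                           library_sizes=library_sizes, seed=cfg.seed,
                           config=cfg)
    return SimResult(matrices=matrices, catalog=catalog,
                     metabolites=metabolites, truth=truth)


def simulate_null_profiles(
    n_sources: int,
    n_targets: int,
    axis: StageAxis = StageAxis(),
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flat, archetype-free RPKM profiles with iid log-normal noise.

    Every series is 2^(baseline + N(0, noise_sd)) per stage with no
    temporal structure, so all source-target pairs satisfy the null of
    zero correlation (exactly Gaussian on the log2 scale).  Used for
    type-I-error calibration of the significance rule.
    """
    rng = np.random.default_rng(seed)
    n = len(axis)

    def block(prefix: str, rows: int) -> pd.DataFrame:
        base = rng.uniform(3.0, 7.0, size=rows)[:, None]
        log2x = base + rng.normal(0.0, noise_sd, size=(rows, n))
        return pd.DataFrame(np.power(2.0, log2x),
                            index=[f"{prefix}{i + 1:05d}" for i in range(rows)],
                            columns=list(axis.stages))

    return block("NS", n_sources), block("NT", n_targets)


@dataclass(frozen=True)
class RecoveryMetrics:
    sensitivity: float
    fdp: float
    sign_accuracy: float
    n_planted: int
    n_called: int
    n_recovered: int


def recovery_metrics(
    truth: SyntheticTruth,
    records: Iterable[CorrelationRecord],
) -> RecoveryMetrics:
    """Score screen output against the planted links.

    A pair is *called* when at least one of its records is significant.
    sensitivity = recovered planted links / planted links; FDP = false
    calls / all calls (0 when nothing is called); sign accuracy is the
    fraction of recovered links whose observed correlation sign matches
    the planted sign.
    """
    records = list(records)
    planted = truth.link_set()
    if not planted:
        raise ValueError("truth contains no planted links")
    truth_ids = {i for pair in planted for i in pair}
    record_ids = {r.source_id for r in records} | {r.target_id for r in records}
    if not (truth_ids & record_ids):
        raise ValueError("record and truth id spaces are disjoint")
    called_sign: dict[tuple[str, str], str] = {}
    for rec in records:
        if rec.significant:
            called_sign[(rec.source_id, rec.target_id)] = rec.sign or ""
    called = set(called_sign)
    recovered = called & planted
    signs = truth.sign_of()
    n_sign_ok = sum(
        (signs[pair] > 0) == (called_sign[pair] == "positive")
        for pair in recovered)
    return RecoveryMetrics(
        sensitivity=len(recovered) / len(planted),
        fdp=(len(called - planted) / len(called)) if called else 0.0,
        sign_accuracy=(n_sign_ok / len(recovered)) if recovered else float("nan"),
        n_planted=len(planted),
        n_called=len(called),
        n_recovered=len(recovered),
    )
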