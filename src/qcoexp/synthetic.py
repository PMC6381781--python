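"""Synthetic expression matrices with planted co-expression modules.

The generator emulates a normalized (log-scale) microarray compendium:
each gene has a random baseline mean and independent Gaussian noise across
conditions, and each planted module adds a constant coherent shift
(``effect_size * coherent_sign``) to its bait and partners on exactly its
condition subset. Because downstream discretization is rank-based, only
the shift-to-noise ratio matters, not the absolute scale.

Defaults mirror the screening study conditions this package targets: 93
conditions (the switchgrass compendium size), 500 genes, 14 bait-anchored
modules of 5 partners each on random quarter-size condition subsets, with
a shift of twice the noise SD.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import BaitSet, ExpressionMatrix, ValidationError

__all__ = [
    "ModuleSpec",
    "SyntheticSpec",
    "PlantedPair",
    "generate_matrix",
    "generate_null_pairs",
    "write_truth",
    "load_spec",
    "save_spec",
    "calibrate_min_bf",
    "evaluate_planted_recovery",
    "evaluate_method_contrast",
    "evaluate_null_calibration",
]


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: a bait, its partners, and their shared shift.

    ``condition_subset`` is either an explicit tuple of condition IDs or a
    fraction in (0, 1] drawn at generation time from the module's RNG.
    """

    bait_id: str
    partner_ids: tuple[str, ...]
    condition_subset: tuple[str, ...] | float = 0.25
    effect_size: float = 2.0
    coherent_sign: int = 1

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValidationError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.coherent_sign not in (-1, 1):
            raise ValidationError(f"coherent_sign must be +-1, got {self.coherent_sign}")
        if self.bait_id in self.partner_ids:
            raise ValidationError(f"bait {self.bait_id!r} repeated among its partners")
        if isinstance(self.condition_subset, float) and not 0.0 < self.condition_subset <= 1.0:
            raise ValidationError(
                f"subset fraction must be in (0, 1], got {self.condition_subset}"
            )


def _default_modules(
    n_baits: int = 14,
    n_partners: int = 5,
    subset_fraction: float = 0.25,
    effect_size: float = 2.0,
) -> tuple[ModuleSpec, ...]:
    mods = []
    for i in range(n_baits):
        bait = f"B{i + 1:02d}"
        partners = tuple(f"{bait}P{j + 1}" for j in range(n_partners))
        mods.append(
            ModuleSpec(
                bait_id=bait,
                partner_ids=partners,
                condition_subset=subset_fraction,
                effect_size=effect_size,
            )
        )
    return tuple(mods)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic compendium."""

    n_genes: int = 500
    n_conditions: int = 93
    modules: tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        # noise_sd = 0 is allowed as a degenerate boundary: baseline cells are
        # then exactly tied, so only planted shifts survive discretization
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_conditions < 2 or self.n_genes < 1:
            raise ValidationError("need >= 1 gene and >= 2 conditions")
        named = [m.bait_id for m in self.modules] + [
            p for m in self.modules for p in m.partner_ids
        ]
        if len(named) > self.n_genes:
            raise ValidationError(
                f"{len(named)} module genes exceed n_genes = {self.n_genes}"
            )
        for m in self.modules:
            if isinstance(m.condition_subset, tuple) and len(m.condition_subset) > self.n_conditions:
                raise ValidationError(
                    f"module {m.bait_id!r}: subset larger than n_conditions"
                )


@dataclass(frozen=True)
class PlantedPair:
    """Ground-truth record of one planted (bait, partner) relationship."""

    bait_id: str
    partner_id: str
    conditions: frozenset[str]
    effect_size: float
    coherent_sign: int


def _condition_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def generate_matrix(spec: SyntheticSpec) -> tuple[ExpressionMatrix, list[PlantedPair]]:
    """Draw a matrix and return it with the planted-pair truth record.

    Identical spec and seed give identical output. Module genes keep their
    spec names; filler genes are ``G0001``... Condition subsets given as
    fractions are sampled without replacement from the module RNG.
    """
    rng = np.random.default_rng(spec.rng_seed)
    conditions = _condition_ids(spec.n_conditions)
    module_genes: list[str] = []
    for m in spec.modules:
        for g in (m.bait_id, *m.partner_ids):
            if g not in module_genes:
                module_genes.append(g)
    n_filler = spec.n_genes - len(module_genes)
    gene_ids = module_genes + [f"G{i + 1:04d}" for i in range(n_filler)]

    means = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)
    values = means[:, None] + rng.normal(0.0, spec.noise_sd, (spec.n_genes, spec.n_conditions))

    index_of = {g: i for i, g in enumerate(gene_ids)}
    cond_index = {c: i for i, c in enumerate(conditions)}
    truth: list[PlantedPair] = []
    for m in spec.modules:
        if isinstance(m.condition_subset, float):
            size = int(round(m.condition_subset * spec.n_conditions))
            if size < 1:
                raise ValidationError(f"module {m.bait_id!r}: empty condition subset")
            subset = tuple(
                conditions[i]
                for i in sorted(rng.choice(spec.n_conditions, size=size, replace=False))
            )
        else:
            unknown = [c for c in m.condition_subset if c not in cond_index]
            if unknown:
                raise ValidationError(f"module {m.bait_id!r}: unknown conditions {unknown}")
            subset = tuple(m.condition_subset)
        cols = [cond_index[c] for c in subset]
        shift = m.effect_size * m.coherent_sign
        for g in (m.bait_id, *m.partner_ids):
            values[index_of[g], cols] += shift
        for p in m.partner_ids:
            truth.append(
                PlantedPair(
                    bait_id=m.bait_id,
                    partner_id=p,
                    conditions=frozenset(subset),
                    effect_size=m.effect_size,
                    coherent_sign=m.coherent_sign,
                )
            )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids), columns=pd.Index(conditions))
    )
    return matrix, truth


def generate_null_pairs(
    n_pairs: int,
    n_conditions: int,
    level_frequencies: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """IID discretized vector pairs for null calibration.

    Returns two ``(n_pairs, n_conditions)`` integer arrays whose entries
    are drawn independently from ``level_frequencies`` (default the sparse
    microarray profile {-1: 0.06, 0: 0.88, +1: 0.06}). Under condition
    permutation the expected BF of a pair is ``n * sum_k f_k^2`` over
    non-zero levels ``k``.
    """
    if level_frequencies is None:
        level_frequencies = {-1: 0.06, 0: 0.88, 1: 0.06}
    levels = np.array(sorted(level_frequencies), dtype=np.int64)
    freqs = np.array([level_frequencies[k] for k in levels], dtype=float)
    if not np.isclose(freqs.sum(), 1.0):
        raise ValidationError(f"level frequencies sum to {freqs.sum():g}, not 1")
    if (freqs < 0).any():
        raise ValidationError("negative level frequency")
    rng = np.random.default_rng(seed)
    a = rng.choice(levels, size=(n_pairs, n_conditions), p=freqs)
    b = rng.choice(levels, size=(n_pairs, n_conditions), p=freqs)
    return a, b


def write_truth(truth: list[PlantedPair], path: str | Path) -> None:
    """Write the planted-pair record as a TSV (support as comma-joined IDs)."""
    with open(path, "w") as fh:
        fh.write("bait_id\tpartner_id\teffect_size\tcoherent_sign\tconditions\n")
        for t in truth:
            fh.write(
                f"{t.bait_id}\t{t.partner_id}\t{t.effect_size:g}\t"
                f"{t.coherent_sign}\t{','.join(sorted(t.conditions))}\n"
            )


def save_spec(spec: SyntheticSpec, path: str | Path) -> None:
    doc = {
        "n_genes": spec.n_genes,
        "n_conditions": spec.n_conditions,
        "noise_sd": spec.noise_sd,
        "baseline_mean": spec.baseline_mean,
        "baseline_sd": spec.baseline_sd,
        "rng_seed": spec.rng_seed,
        "modules": [
            {
                "bait_id": m.bait_id,
                "partner_ids": list(m.partner_ids),
                "condition_subset": (
                    list(m.condition_subset)
                    if isinstance(m.condition_subset, tuple)
                    else m.condition_subset
                ),
                "effect_size": m.effect_size,
                "coherent_sign": m.coherent_sign,
            }
            for m in spec.modules
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_spec(path: str | Path) -> SyntheticSpec:
    doc = yaml.safe_load(Path(path).read_text())
    modules = tuple(
        ModuleSpec(
            bait_id=m["bait_id"],
            partner_ids=tuple(m["partner_ids"]),
            condition_subset=(
                tuple(m["condition_subset"])
                if isinstance(m["condition_subset"], list)
                else float(m["condition_subset"])
            ),
            effect_size=float(m.get("effect_size", 2.0)),
            coherent_sign=int(m.get("coherent_sign", 1)),
        )
        for m in doc.get("modules", [])
    ) or _default_modules()
    return SyntheticSpec(
        n_genes=int(doc.get("n_genes", 500)),
        n_conditions=int(doc.get("n_conditions", 93)),
        modules=modules,
        noise_sd=float(doc.get("noise_sd", 1.0)),
        baseline_mean=float(doc.get("baseline_mean", 8.0)),
        baseline_sd=float(doc.get("baseline_sd", 2.0)),
        rng_seed=int(doc.get("rng_seed", 0)),
    )


# ---------------------------------------------------------------------------
# benchmark evaluations against the planted truth
# ---------------------------------------------------------------------------


def calibrate_min_bf(
    a: np.ndarray,
    b: np.ndarray,
    per_pair_fpr: float,
    n_sim: int = 20_000,
    seed: int = 0,
) -> int:
    """Smallest BF floor whose permutation-null tail is <= ``per_pair_fpr``.

    ``a`` and ``b`` are representative level vectors (the null depends only
    on their level margins). Used to set a screen's ``min_bf`` for a target
    per-pair false-positive rate without touching the planted truth.
    """
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(b, (n_sim, b.size)).copy(), axis=1)
    null = ((perms == a) & (a != 0)).sum(axis=1)
    for threshold in range(0, int(a.size) + 2):
        if (null >= threshold).mean() <= per_pair_fpr:
            return threshold
    return int(a.size) + 1


def evaluate_planted_recovery(
    spec: SyntheticSpec | None = None,
    q: float | None = None,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    fp_budget: float = 0.05,
    n_seeds: int = 10,
    base_seed: int = 0,
) -> dict:
    """Sensitivity / false-edge fraction of the screen on planted modules.

    For each seed a matrix is drawn from ``spec`` (default study spec),
    discretized with ``q`` matched to the planted condition-subset
    prevalence, and screened with the BF floor calibrated so that the
    expected share of false edges among calls stays within ``fp_budget``
    under full sensitivity. Averages over ``n_seeds`` replicates.
    """
    from .coexpression import ScreenParams, screen_baits
    from .discretize import DiscretizationParams, discretize_matrix

    spec = spec or SyntheticSpec()
    if q is None:
        fractions = [
            m.condition_subset
            for m in spec.modules
            if isinstance(m.condition_subset, float)
        ]
        q = min(float(np.mean(fractions)) if fractions else 0.25, 0.45)
    bait_ids = tuple(m.bait_id for m in spec.modules)
    n_partners = sum(len(m.partner_ids) for m in spec.modules)
    n_pairs = len(bait_ids) * (spec.n_genes - 1)
    per_pair_fpr = (fp_budget / (1.0 - fp_budget)) * n_partners / max(n_pairs - n_partners, 1)

    sens, fp_frac, n_called_all, thresholds = [], [], [], []
    for i in range(n_seeds):
        seed_i = (base_seed + i) & 0x7FFFFFFF
        spec_i = dataclasses.replace(spec, rng_seed=seed_i)
        matrix, truth = generate_matrix(spec_i)
        d = discretize_matrix(matrix, DiscretizationParams(q=q))
        filler = next(g for g in matrix.gene_ids if g not in bait_ids)
        min_bf = calibrate_min_bf(
            d.row(bait_ids[0]), d.row(filler), per_pair_fpr, seed=seed_i + 1
        )
        thresholds.append(min_bf)
        params = ScreenParams(
            min_bf=min_bf, alpha=alpha, n_permutations=n_permutations, rng_seed=seed_i
        )
        edges = screen_baits(d, BaitSet(bait_ids, "planted"), params)
        called = {(e.bait_id, e.partner_id) for e in edges}
        truth_pairs = {(t.bait_id, t.partner_id) for t in truth}
        sens.append(len(called & truth_pairs) / len(truth_pairs))
        fp_frac.append(len(called - truth_pairs) / max(len(called), 1))
        n_called_all.append(len(called))
    return {
        "sensitivity": float(np.mean(sens)),
        "false_edge_fraction": float(np.mean(fp_frac)),
        "n_called": float(np.mean(n_called_all)),
        "q": q,
        "min_bf": thresholds,
        "n_seeds": n_seeds,
        "n_planted_pairs": n_partners,
    }


def evaluate_method_contrast(
    spec: SyntheticSpec | None = None,
    q: float | None = None,
    n_seeds: int = 3,
    base_seed: int = 0,
) -> dict:
    """Percentile ranks of planted partners under BF vs Pearson scoring.

    For every bait the raw BF and Pearson scores against all other genes
    are ranked; each planted partner's percentile under each method is
    recorded and the medians over all planted pairs (pooled over seeds)
    are returned.
    """
    from scipy.stats import rankdata

    from .discretize import DiscretizationParams, discretize_matrix

    spec = spec or SyntheticSpec()
    if q is None:
        fractions = [
            m.condition_subset
            for m in spec.modules
            if isinstance(m.condition_subset, float)
        ]
        q = min(float(np.mean(fractions)) if fractions else 0.25, 0.45)
    bf_pct, pcc_pct = [], []
    for i in range(n_seeds):
        spec_i = dataclasses.replace(spec, rng_seed=(base_seed + i) & 0x7FFFFFFF)
        matrix, truth = generate_matrix(spec_i)
        d = discretize_matrix(matrix, DiscretizationParams(q=q))
        levels = d.levels.to_numpy(dtype=np.int64)
        vals = matrix.values.to_numpy(dtype=float)
        centered = vals - vals.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        norms[norms == 0] = np.nan
        unit = centered / norms[:, None]
        gene_index = {g: j for j, g in enumerate(matrix.gene_ids)}
        by_bait: dict[str, list[str]] = {}
        for t in truth:
            by_bait.setdefault(t.bait_id, []).append(t.partner_id)
        for bait, partners in by_bait.items():
            bi = gene_index[bait]
            others = np.array([j for j in range(len(gene_index)) if j != bi])
            a = levels[bi]
            bf = ((levels[others] == a) & (a != 0)).sum(axis=1)
            pcc = unit[others] @ unit[bi]
            bf_rank = rankdata(bf) / others.size * 100.0
            pcc_rank = rankdata(np.nan_to_num(pcc, nan=-2.0)) / others.size * 100.0
            pos = {int(j): n for n, j in enumerate(others)}
            for p in partners:
                n = pos[gene_index[p]]
                bf_pct.append(bf_rank[n])
                pcc_pct.append(pcc_rank[n])
    return {
        "median_bf_percentile": float(np.median(bf_pct)),
        "median_pcc_percentile": float(np.median(pcc_pct)),
        "frac_bf_above_95": float(np.mean(np.asarray(bf_pct) > 95.0)),
        "frac_pcc_above_95": float(np.mean(np.asarray(pcc_pct) > 95.0)),
        "n_pairs": len(bf_pct),
    }


def evaluate_null_calibration(
    n_mean_pairs: int = 10_000,
    n_fpr_pairs: int = 2000,
    n_conditions: int = 93,
    level_frequencies: dict[int, float] | None = None,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Empirical null mean BF vs the closed form, and edge-calling FPR.

    Draws iid discretized pairs, checks the mean BF against
    ``n * sum_k f_k^2`` (non-zero levels), and measures the fraction of
    independent pairs called at level ``alpha`` by the randomized
    permutation p-value.
    """
    from .coexpression import ScreenParams, bf_null_pvalue

    freqs = level_frequencies or {-1: 0.06, 0: 0.88, 1: 0.06}
    a, b = generate_null_pairs(n_mean_pairs, n_conditions, freqs, seed=seed)
    bf = ((a == b) & (a != 0)).sum(axis=1)
    closed_form = n_conditions * sum(f * f for k, f in freqs.items() if k != 0)
    se_mean = float(bf.std(ddof=1) / np.sqrt(n_mean_pairs))

    params = ScreenParams(
        alpha=alpha, n_permutations=n_permutations, rng_seed=seed, tie_break="randomized"
    )
    a2, b2 = generate_null_pairs(n_fpr_pairs, n_conditions, freqs, seed=seed + 1)
    calls = 0
    for i in range(n_fpr_pairs):
        obs = int(((a2[i] == b2[i]) & (a2[i] != 0)).sum())
        p = bf_null_pvalue(obs, a2[i], b2[i], params, f"pair{i}", "partner")
        calls += p <= alpha
    fpr = calls / n_fpr_pairs
    return {
        "mean_bf": float(bf.mean()),
        "closed_form_mean_bf": float(closed_form),
        "mean_bf_se": se_mean,
        "fpr": float(fpr),
        "alpha": alpha,
        "fpr_se": float(np.sqrt(alpha * (1 - alpha) / n_fpr_pairs)),
        "n_mean_pairs": n_mean_pairs,
        "n_fpr_pairs": n_fpr_pairs,
    }
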