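"""Synthetic designed-experiment expression matrices with ground truth.

The generator emulates the variance structure of an in-vivo hippocampal
conditioning study: 8 condition groups x 9 replicates (72 samples), two
dominant per-sample unwanted factors (targeting ~40% and ~17% of the
centered variance) concentrated on a shared, correlated gene module, a
circadian component (~8%) affecting ~1000 genes, and small treatment
effects (log2 fold changes 0.3-0.5) planted at two conditions whose overlap
is confined to upregulated genes.  Per gene g and sample s the model is
additive:

    X[g,s] = baseline[g]
           + sum_f score_f[g] * loading_f[s]          (unwanted factors)
           + a[g] * cos(2*pi*ZT[s]/period - phi[g])   (circadian)
           + effect[g, group[s]]                      (treatment)
           + eps[g,s],   eps ~ N(0, noise_sd^2)

Unwanted-factor loadings are heavy-tailed (Student-t, df=3) per sample to
mimic a few extreme animals; loadings are centered and orthogonalized
against each other and against the circadian sample profile, so component
energies add and the target variance fractions can be calibrated exactly
(factor scales are solved analytically from the noise+effect energy).
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import ExpressionMatrix

DEFAULT_DESIGN = [
    ("CC30'", 3.5, 9),
    ("FC30'", 3.5, 9),
    ("CC4", 7.0, 9),
    ("FC4", 7.0, 9),
    ("CC12", 15.0, 9),
    ("FC12", 15.0, 9),
    ("FC24", 3.5, 9),
    ("RT30'", 3.5, 9),
]


@dataclass
class FactorSpec:
    """One unwanted per-sample factor.

    ``variance_fraction`` is the share of total centered variance the factor
    should occupy; ``module_size`` genes carry ``module_energy_share`` of the
    factor energy (the rest is spread over all remaining genes, modelling a
    global systemic artifact); per-sample loadings are Student-t with
    ``loading_df`` degrees of freedom.
    """

    variance_fraction: float
    module_size: int = 172
    loading_df: float = 3.0
    module_energy_share: float = 0.5


@dataclass
class CircadianSpec:
    variance_fraction: float = 0.08
    module_size: int = 1000
    period: float = 24.0
    amplitude: float = 0.3      # log2 units, pre-calibration scale
    phase_sd: float = np.pi / 6  # genes peak in a loose phase cluster


@dataclass
class EffectSpec:
    """Planted treatment effects at one condition.

    ``share_up_with`` names an earlier effect spec whose upregulated genes
    (and signed effects) this condition reuses, so that the overlap between
    the two conditions is concentrated in upregulated genes.
    """

    condition: str
    n_up: int
    n_down: int
    log2fc_range: tuple = (0.3, 0.5)
    share_up_with: str | None = None


@dataclass
class SimConfig:
    n_genes: int = 2000
    design: list = field(default_factory=lambda: list(DEFAULT_DESIGN))
    factors: list = field(
        default_factory=lambda: [
            # the dominant factor is a diffuse systemic artifact (strongest
            # on the module but touching every gene); the second is mostly
            # module-concentrated.  The asymmetric shares keep the
            # module-correlated scores globally orthogonalizable.
            FactorSpec(0.40, module_energy_share=0.3),
            FactorSpec(0.17, module_energy_share=0.7),
        ]
    )
    factors_share_module: bool = True
    factor_score_correlation: float = 0.95
    circadian: CircadianSpec = field(default_factory=CircadianSpec)
    effects: list = field(
        default_factory=lambda: [
            EffectSpec("FC30'", 100, 83),
            EffectSpec("RT30'", 100, 83, share_up_with="FC30'"),
        ]
    )
    noise_sd: float = 0.15
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        groups = [g for g, _, _ in self.design]
        if len(set(groups)) != len(groups):
            raise ConfigurationError("design contains duplicate group labels")
        for g, zt, n in self.design:
            if n < 2:
                raise ConfigurationError(
                    f"design: group {g!r} has n_replicates {n} < 2"
                )
            if not 0 <= zt < 24:
                raise ConfigurationError(f"design: group {g!r} zt outside [0, 24)")
        fractions = [f.variance_fraction for f in self.factors]
        if self.circadian.variance_fraction:
            fractions.append(self.circadian.variance_fraction)
        for v in fractions:
            if not 0 <= v < 1:
                raise ConfigurationError(
                    "factors/circadian: variance_fraction must lie in [0, 1)"
                )
        if sum(fractions) >= 1:
            raise ConfigurationError(
                "factors/circadian: variance fractions must sum to < 1"
            )
        sizes = [f.module_size for f in self.factors]
        if self.circadian.variance_fraction:
            sizes.append(self.circadian.module_size)
        if any(m > self.n_genes for m in sizes):
            raise ConfigurationError("module_size exceeds n_genes")
        if self.factors_share_module and len(self.factors) >= 2:
            # score vectors of shared-module factors must stay globally
            # orthogonal (they model orthogonal principal components that
            # correlate only on the module subset); the background part must
            # be able to cancel the module correlation
            rho = self.factor_score_correlation
            s1 = self.factors[0].module_energy_share
            for f in self.factors[1:]:
                sj = f.module_energy_share
                if rho ** 2 * s1 * sj > (1 - s1) * (1 - sj) + 1e-9:
                    raise ConfigurationError(
                        "factor_score_correlation/module_energy_share: "
                        "module-correlated scores cannot be made globally "
                        "orthogonal (reduce correlation or module share)"
                    )
        needed = self._role_gene_count()
        if needed > self.n_genes:
            raise ConfigurationError(
                f"effects: planted roles need {needed} genes > n_genes"
            )
        seen = {}
        for e in self.effects:
            if e.condition not in groups:
                raise ConfigurationError(
                    f"effects: condition {e.condition!r} not in design"
                )
            if e.n_up < 0 or e.n_down < 0:
                raise ConfigurationError("effects: counts must be non-negative")
            lo, hi = e.log2fc_range
            if not 0 < lo <= hi:
                raise ConfigurationError("effects: log2fc_range must be positive")
            if e.share_up_with is not None:
                ref = seen.get(e.share_up_with)
                if ref is None:
                    raise ConfigurationError(
                        f"effects: share_up_with {e.share_up_with!r} "
                        "must name an earlier effect"
                    )
                if e.n_up != ref.n_up:
                    raise ConfigurationError(
                        "effects: shared up-set requires matching n_up"
                    )
            seen[e.condition] = e

    def _role_gene_count(self) -> int:
        module = 0
        if self.factors:
            if self.factors_share_module:
                module = max(f.module_size for f in self.factors)
            else:
                module = sum(f.module_size for f in self.factors)
        circ = self.circadian.module_size if self.circadian.variance_fraction else 0
        eff = sum(
            (0 if e.share_up_with else e.n_up) + e.n_down for e in self.effects
        )
        return module + circ + eff


@dataclass
class SynthTruth:
    """Ground truth of one generated dataset.

    ``de_genes`` maps condition -> {gene id: signed log2 effect};
    ``factor_loadings`` holds the per-sample loading of each unwanted factor
    plus the raw circadian sample profile (column ``circadian``).
    """

    de_genes: dict
    unwanted_module: set
    circadian_module: set
    factor_loadings: pd.DataFrame

    def __eq__(self, other):
        if not isinstance(other, SynthTruth):
            return NotImplemented
        return (
            self.de_genes == other.de_genes
            and self.unwanted_module == other.unwanted_module
            and self.circadian_module == other.circadian_module
            and self.factor_loadings.sort_index()
            .sort_index(axis=1)
            .equals(other.factor_loadings.sort_index().sort_index(axis=1))
        )


def _build_samples(design) -> pd.DataFrame:
    rows = []
    for group, zt, n in design:
        for r in range(n):
            rows.append((f"{group}_r{r + 1}", group, float(zt), f"day{r + 1}"))
    df = pd.DataFrame(rows, columns=["sample", "group", "zt", "batch"])
    return df.set_index("sample")


def _orthonormalize(v: np.ndarray, basis: list) -> np.ndarray | None:
    """Center v, project out basis vectors, normalize; None if degenerate."""
    v = v - v.mean()
    for b in basis:
        v = v - (v @ b) * b
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        return None
    return v / norm


def _factor_scores(mod_raw, bg_raw, mask, share, target, prev_scores):
    """Per-gene score vector of one unwanted factor.

    Module genes carry ``share`` of the total score energy ``target``; the
    background part is constructed so the full score vector is exactly
    orthogonal to every previously built factor's scores (principal
    components are orthogonal across all genes even when their module
    subsets correlate strongly).
    """
    n_g = mask.size
    score = np.zeros(n_g)
    share_eff = share if mask.any() else 0.0
    if mask.any():
        mod_norm = np.linalg.norm(mod_raw)
        if mod_norm > 0:
            score[mask] = mod_raw * np.sqrt(share_eff * target) / mod_norm
    supp = ~mask
    bg_energy = (1.0 - share_eff) * target
    if bg_energy <= 0 or not supp.any():
        return score
    if prev_scores:
        P = np.array([s[supp] for s in prev_scores])
        d = -np.array([float(score @ s) for s in prev_scores])
        G = P @ P.T
        coef, *_ = np.linalg.lstsq(G, d, rcond=None)
        x0 = P.T @ coef
        r2 = bg_energy - float(x0 @ x0)
        if r2 < -1e-9 * bg_energy:
            raise ConfigurationError(
                "factors: module correlation too strong for orthogonal "
                "background construction (reduce module_energy_share or "
                "factor_score_correlation)"
            )
        resid = bg_raw[supp].astype(float)
        proj, *_ = np.linalg.lstsq(G, P @ resid, rcond=None)
        resid = resid - P.T @ proj  # exact projection off span(P)
        rnorm = np.linalg.norm(resid)
        x = x0 + (np.sqrt(max(r2, 0.0)) / rnorm) * resid if rnorm > 0 else x0
        score[supp] = x
    else:
        bg = bg_raw[supp].astype(float)
        score[supp] = bg * np.sqrt(bg_energy) / np.linalg.norm(bg)
    return score


def generate_dataset(config: SimConfig):
    """Generate an expression matrix plus ground truth per the config.

    Returns ``(ExpressionMatrix, SynthTruth)``.  Bitwise deterministic for a
    given config (all randomness flows from ``config.seed`` in fixed order).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _build_samples(config.design)
    n_s = len(samples)
    n_g = config.n_genes
    gene_ids = np.array([f"g{i + 1:05d}" for i in range(n_g)])
    zt = samples["zt"].to_numpy()
    group = samples["group"].to_numpy()

    # ---- gene role assignment (disjoint modules for clean recovery tests)
    perm = rng.permutation(n_g)
    ptr = 0

    def take(n):
        nonlocal ptr
        sel = perm[ptr:ptr + n]
        ptr += n
        return sel

    factor_gene_idx = []
    if config.factors:
        if config.factors_share_module:
            shared = take(max(f.module_size for f in config.factors))
            factor_gene_idx = [shared[: f.module_size] for f in config.factors]
        else:
            factor_gene_idx = [take(f.module_size) for f in config.factors]
    circ_active = config.circadian.variance_fraction > 0
    circ_idx = take(config.circadian.module_size) if circ_active else np.array([], int)

    # ---- baseline
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_g)

    # ---- raw factor scores (module + background), in config order
    raw_scores = []
    prev_module_scores = None
    for f, idx in zip(config.factors, factor_gene_idx):
        mod = rng.standard_normal(len(idx))
        if (
            config.factors_share_module
            and prev_module_scores is not None
            and len(mod) == len(prev_module_scores)
        ):
            rho = config.factor_score_correlation
            mod = rho * prev_module_scores + np.sqrt(1 - rho ** 2) * mod
        prev_module_scores = mod
        bg = rng.standard_normal(n_g)
        mask = np.zeros(n_g, bool)
        mask[idx] = True
        raw_scores.append((mod, bg, mask))

    # ---- factor loadings: heavy-tailed, centered, mutually orthonormal and
    # orthogonal to the circadian sample profile
    basis = []
    if circ_active:
        w = 2 * np.pi / config.circadian.period
        for vec in (np.cos(w * zt), np.sin(w * zt)):
            u = _orthonormalize(vec, basis)
            if u is not None:
                basis.append(u)
    n_circ_basis = len(basis)
    loadings = []
    for f in config.factors:
        raw = rng.standard_t(f.loading_df, n_s)
        u = _orthonormalize(raw, basis)
        while u is None:  # essentially impossible, but keep it total
            u = _orthonormalize(rng.standard_t(f.loading_df, n_s), basis)
        basis.append(u)
        loadings.append(u)

    # ---- circadian amplitudes and phases
    if circ_active:
        c = config.circadian
        amp = np.abs(rng.normal(c.amplitude, c.amplitude / 3, len(circ_idx)))
        phase = rng.normal(0.0, c.phase_sd, len(circ_idx))

    # ---- planted effects
    effects = np.zeros((n_g, n_s))
    de_genes: dict = {}
    up_assignments: dict = {}
    for e in config.effects:
        lo, hi = e.log2fc_range
        if e.share_up_with is not None:
            up_idx, up_eff = up_assignments[e.share_up_with]
        else:
            up_idx = take(e.n_up)
            up_eff = rng.uniform(lo, hi, e.n_up)
        down_idx = take(e.n_down)
        down_eff = -rng.uniform(lo, hi, e.n_down)
        up_assignments[e.condition] = (up_idx, up_eff)
        cols = group == e.condition
        effects[np.ix_(up_idx, cols)] += up_eff[:, None]
        effects[np.ix_(down_idx, cols)] += down_eff[:, None]
        mapping = {gene_ids[i]: float(v) for i, v in zip(up_idx, up_eff)}
        mapping.update({gene_ids[i]: float(v) for i, v in zip(down_idx, down_eff)})
        de_genes[e.condition] = mapping

    # ---- noise and energy calibration
    noise = rng.normal(0.0, config.noise_sd, (n_g, n_s))
    base = effects + noise
    base_centered = base - base.mean(axis=1, keepdims=True)
    e_base = float((base_centered ** 2).sum())
    fractions = [f.variance_fraction for f in config.factors]
    if circ_active:
        fractions.append(config.circadian.variance_fraction)
    residual_fraction = 1.0 - sum(fractions)

    X = baseline[:, None] + base
    truth_cols = {}
    prev_score_vectors: list = []
    for f, (mod_raw, bg_raw, mask), ell in zip(
        config.factors, raw_scores, loadings
    ):
        target = f.variance_fraction / residual_fraction * e_base
        if target > 0:
            score = _factor_scores(
                mod_raw, bg_raw, mask, f.module_energy_share, target,
                prev_score_vectors,
            )
            prev_score_vectors.append(score)
            X += np.outer(score, ell)
    for j, ell in enumerate(loadings):
        truth_cols[f"factor{j + 1}"] = ell

    if circ_active:
        C = np.zeros((n_g, n_s))
        w = 2 * np.pi / config.circadian.period
        C[circ_idx] = amp[:, None] * np.cos(w * zt[None, :] - phase[:, None])
        C -= C.mean(axis=1, keepdims=True)
        energy = float((C ** 2).sum())
        target = config.circadian.variance_fraction / residual_fraction * e_base
        if energy > 0 and target > 0:
            C *= np.sqrt(target / energy)
            X += C
        truth_cols["circadian"] = np.cos(w * zt)

    values = pd.DataFrame(X, index=gene_ids, columns=samples.index)
    matrix = ExpressionMatrix(values, samples)
    truth = SynthTruth(
        de_genes=de_genes,
        unwanted_module={gene_ids[i] for idx in factor_gene_idx for i in idx},
        circadian_module={gene_ids[i] for i in circ_idx},
        factor_loadings=pd.DataFrame(truth_cols, index=samples.index)
        if truth_cols
        else pd.DataFrame(index=samples.index),
    )
    return matrix, truth


def pure_null_config(config: SimConfig | None = None, seed: int = 0) -> SimConfig:
    """The default study conditions with no planted treatment effects."""
    cfg = config or SimConfig()
    return replace(cfg, effects=[], seed=seed)


# ---------------------------------------------------------------------------
# truth TSV round-trip


def write_truth(truth: SynthTruth, path) -> None:
    """Serialize ground truth as a TSV, one row per planted signal.

    Roles: ``de`` (gene, condition, signed effect), ``unwanted_module``,
    ``circadian_module``, and ``factor_loading`` rows whose *gene* column
    holds the sample id, *condition* the factor name and *effect* the
    loading value (keeps the file single-schema while lossless).
    """
    rows = []
    for cond in sorted(truth.de_genes):
        for gene in sorted(truth.de_genes[cond]):
            rows.append((gene, "de", cond, repr(truth.de_genes[cond][gene])))
    for gene in sorted(truth.unwanted_module):
        rows.append((gene, "unwanted_module", "", ""))
    for gene in sorted(truth.circadian_module):
        rows.append((gene, "circadian_module", "", ""))
    for col in truth.factor_loadings.columns:
        for sample, val in truth.factor_loadings[col].items():
            rows.append((sample, "factor_loading", col, repr(float(val))))
    with open(path, "w") as fh:
        fh.write("gene\trole\tcondition\teffect\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_truth(path) -> SynthTruth:
    """Inverse of :func:`write_truth`."""
    de: dict = {}
    unwanted: set = set()
    circadian: set = set()
    loadings: dict = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and header.split("\t")[0] != "gene":
            raise ValueError(f"{path}: unexpected truth header")
        for line in fh:
            gene, role, cond, effect = line.rstrip("\n").split("\t")
            if role == "de":
                de.setdefault(cond, {})[gene] = float(effect)
            elif role == "unwanted_module":
                unwanted.add(gene)
            elif role == "circadian_module":
                circadian.add(gene)
            elif role == "factor_loading":
                loadings.setdefault(cond, {})[gene] = float(effect)
            else:
                raise ValueError(f"{path}: unknown role {role!r}")
    ld = pd.DataFrame(loadings) if loadings else pd.DataFrame()
    return SynthTruth(de, unwanted, circadian, ld)
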