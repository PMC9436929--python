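"""Synthetic cohorts, UMI count matrices and variant evidence with planted truth.

The generators emulate the design of a two-cohort human CD8+ T-cell aging
study: a cross-sectional cohort spanning newborn to old age (single blood
draw per donor) and a longitudinal cohort with repeat visits roughly nine
years apart.  Every generated object carries its generating parameters
("planted truth") so downstream estimators can be scored against it:

* per-gene age effects act on the *detection probability* (share of cells
  with a nonzero UMI count), on the *positive-cell expression level*, or on
  both — mirroring the three modes of age-related expression change;
* each cell has a latent ``true_cell_age`` = donor age + subset offset +
  Gaussian jitter (naive cells are planted younger than memory cells);
* somatic-mutation evidence is generated per UMI so that consensus filters
  can separate true variants (consistent alt reads) from artifacts.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; count generation uses one spawned sub-stream
per donor so that subsetting donors does not reshuffle other donors' cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.sparse import csr_matrix

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: group label shared by every cross-sectional cell (single-visit donors form
#: one random-effect group; each longitudinal donor is its own group)
CROSS_SECTIONAL_GROUP = "XS"


class InvalidConfiguration(ValueError):
    """Raised when a generator is called with an inconsistent design."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DonorRecord:
    """A study participant and their aged visits.

    ``cohort`` determines the random-effect grouping downstream: all
    cross-sectional donors share one group, each longitudinal donor is a
    group of its own.
    """

    donor_id: str
    sex: str  # "F" or "M"
    cohort: str  # "cross_sectional" or "longitudinal"
    visits: tuple  # ordered ((visit_id, age_years), ...)

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.cohort not in ("cross_sectional", "longitudinal"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        ages = [a for _, a in self.visits]
        if any(a < 0 for a in ages):
            raise ValueError("ages must be non-negative")
        if self.cohort == "cross_sectional" and len(self.visits) != 1:
            raise ValueError("cross-sectional donors have exactly one visit")
        if self.cohort == "longitudinal":
            if len(self.visits) < 2:
                raise ValueError("longitudinal donors need >=2 visits")
            if any(b <= a for a, b in zip(ages, ages[1:])):
                raise ValueError("visit ages must be strictly increasing")

    @property
    def group_id(self) -> str:
        return (
            CROSS_SECTIONAL_GROUP
            if self.cohort == "cross_sectional"
            else self.donor_id
        )


@dataclass(frozen=True)
class GeneEffectSpec:
    """Planted per-gene age effect.

    ``mode`` names which readout the age effect acts on:

    - ``percentage``: detection probability changes with age
      (``detect_slope`` in probability units per year), positive-cell level
      is flat;
    - ``expression``: positive-cell negative-binomial mean changes with age
      (``level_slope``, relative change per year), detection is flat;
    - ``both``: both readouts change;
    - ``none``: flat in age (background / null gene).

    ``baseline_detect`` is the detection probability at age 0 and
    ``baseline_mean`` the positive-cell NB mean at age 0; ``dispersion`` is
    the NB size parameter.  Positive-cell counts are drawn zero-truncated so
    a "detected" cell always has at least one UMI.
    """

    gene_id: str
    baseline_mean: float
    dispersion: float
    mode: str = "none"
    detect_slope: float = 0.0
    level_slope: float = 0.0
    baseline_detect: float = 0.5
    subset_offsets: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.baseline_mean < 0:
            raise ValueError("baseline_mean must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0.0 <= self.baseline_detect <= 1.0:
            raise ValueError("baseline_detect must be in [0, 1]")
        if self.mode not in ("percentage", "expression", "both", "none"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "none" and (self.detect_slope or self.level_slope):
            raise ValueError("mode='none' requires zero slopes")
        if self.mode == "percentage" and self.level_slope:
            raise ValueError("mode='percentage' requires level_slope=0")
        if self.mode == "expression" and self.detect_slope:
            raise ValueError("mode='expression' requires detect_slope=0")


@dataclass(frozen=True)
class CellSimSpec:
    """Per-visit cell sampling design.

    ``subset_composition`` maps subset label -> (baseline proportion at age
    0, proportion slope per year).  Proportions are clamped to [0, 1] and
    renormalized at every age.  ``subset_age_offsets`` shifts the latent
    cell age per subset (naive below memory); jitter is Gaussian with the
    latent age floored at 0.
    """

    cells_per_visit: int
    subset_composition: Mapping[str, tuple]
    cell_age_jitter_sd: float = 5.0
    subset_age_offsets: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.cells_per_visit <= 0:
            raise ValueError("cells_per_visit must be positive")
        total = sum(b for b, _ in self.subset_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"baseline subset proportions must sum to 1, got {total}"
            )


@dataclass(frozen=True)
class BurdenModel:
    """Log-linear model for the expected true-mutation count of a cell.

    lambda = rate0 * exp(c_umi * zlog(total_umi) + c_cov * zlog(cell_cov)
                         + c_exo * zlog(exome_cov) + c_age * true_cell_age)

    where ``zlog`` is the mean-centered log of the covariate.  ``rate0`` is
    the expected burden of a typical age-0 cell; an all-zero model (rate0=0)
    produces no mutations.
    """

    rate0: float = 1.0
    coef_log_umi: float = 0.0
    coef_log_cell_cov: float = 0.0
    coef_log_exome_cov: float = 0.0
    coef_cell_age: float = 0.0


# ---------------------------------------------------------------------------
# study-design defaults
# ---------------------------------------------------------------------------


def default_subset_composition() -> dict:
    """Four major subsets with a declining naive share (-0.5 pp/year)."""
    return {
        "Na": (0.50, -0.005),
        "SCM": (0.14, 0.002),
        "CM": (0.18, 0.0015),
        "EM": (0.18, 0.0015),
    }


def default_subset_age_offsets() -> dict:
    """Latent cell-age offsets in years; naive planted youngest."""
    return {"Na": -8.0, "SCM": 0.0, "CM": 2.0, "EM": 5.0}


def default_gene_panel(
    n_percentage: int = 8,
    n_expression: int = 8,
    n_both: int = 4,
    n_null: int = 10,
    n_background: int = 140,
    seed: int = 0,
) -> list:
    """Default gene panel: planted age genes plus flat background genes.

    Background genes carry most of the library so that per-cell UMI totals
    land inside the standard QC window; planted effect sizes give about a
    10-15% span change over a 90-year cohort.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBEEF)))
    specs: list[GeneEffectSpec] = []
    for i in range(n_percentage):
        specs.append(
            GeneEffectSpec(
                f"PCT{i + 1:03d}", baseline_mean=3.0, dispersion=4.0,
                mode="percentage", detect_slope=(0.12 / 90) * (-1) ** i,
                baseline_detect=0.45 if i % 2 else 0.30,
            )
        )
    for i in range(n_expression):
        specs.append(
            GeneEffectSpec(
                f"EXP{i + 1:03d}", baseline_mean=6.0, dispersion=4.0,
                mode="expression", level_slope=0.009 * (-1) ** i,
                baseline_detect=0.70,
            )
        )
    for i in range(n_both):
        specs.append(
            GeneEffectSpec(
                f"BOTH{i + 1:03d}", baseline_mean=5.0, dispersion=4.0,
                mode="both", detect_slope=0.12 / 90, level_slope=0.007,
                baseline_detect=0.30,
            )
        )
    for i in range(n_null):
        specs.append(
            GeneEffectSpec(
                f"NULL{i + 1:03d}", baseline_mean=3.0, dispersion=4.0,
                mode="none", baseline_detect=0.40,
            )
        )
    means = rng.lognormal(mean=np.log(8.0), sigma=0.4, size=n_background)
    for i in range(n_background):
        specs.append(
            GeneEffectSpec(
                f"BG{i + 1:04d}", baseline_mean=float(means[i]),
                dispersion=5.0, mode="none", baseline_detect=0.85,
            )
        )
    return specs


def clock_gene_panel(
    n_level: int = 25,
    n_detect: int = 25,
    n_null: int = 30,
    n_background: int = 100,
    seed: int = 0,
) -> list:
    """Gene panel for cell-age clock studies: 50 age-informative genes.

    Half the signal genes carry a positive-cell level effect (rising
    +0.022/y or declining -0.009/y relative change; the declining slope
    keeps the NB mean positive over the attainable cell-age range), half a
    detection effect spanning 0.6 in probability over 90 years.  Null and
    background genes are flat.  Effects act on the latent cell age, so the
    panel encodes both the donor's age and the within-donor naive/memory
    ordering.
    """
    specs: list[GeneEffectSpec] = []
    for i in range(n_level):
        specs.append(
            GeneEffectSpec(
                f"CLKL{i + 1:03d}", baseline_mean=8.0, dispersion=8.0,
                mode="expression",
                level_slope=0.022 if i % 2 else -0.009,
                baseline_detect=0.85,
            )
        )
    for i in range(n_detect):
        specs.append(
            GeneEffectSpec(
                f"CLKP{i + 1:03d}", baseline_mean=4.0, dispersion=8.0,
                mode="percentage",
                detect_slope=(0.6 / 90) * (-1) ** (i % 2),
                baseline_detect=0.5 if i % 2 else 0.12,
            )
        )
    for i in range(n_null):
        specs.append(
            GeneEffectSpec(
                f"CLKN{i + 1:03d}", baseline_mean=4.0, dispersion=8.0,
                baseline_detect=0.5,
            )
        )
    specs.extend(
        default_gene_panel(0, 0, 0, 0, n_background=n_background, seed=seed)
    )
    return specs


def clock_study(seed: int = 0, n_cross: int = 14, n_long: int = 6,
                cells_per_visit: int = 200):
    """Standard clock study conditions: 20 donors, ~200 cells per donor.

    Returns ``(donors, gene_specs, CellSimSpec)`` ready for
    :func:`generate_counts`.
    """
    donors = generate_cohort(n_cross, n_long, (0.0, 90.0), 2, 9.0, seed=seed)
    specs = clock_gene_panel(seed=seed)
    sim = CellSimSpec(
        cells_per_visit=cells_per_visit,
        subset_composition=default_subset_composition(),
        subset_age_offsets=default_subset_age_offsets(),
        seed=seed,
    )
    return donors, specs, sim


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    n_cross: int,
    n_long: int,
    age_range: tuple = (0.0, 90.0),
    visits_per_long: int = 2,
    visit_gap_mean: float = 9.0,
    seed: int = 0,
    long_first_visit_range: tuple = (30.0, 69.0),
) -> list:
    """Generate a synthetic donor cohort.

    ``n_cross`` single-visit donors with ages uniform over ``age_range``
    and ``n_long`` donors with ``visits_per_long`` visits separated by gaps
    of mean ``visit_gap_mean`` years.  Sexes alternate within each cohort so
    they are balanced up to parity.  Deterministic given ``seed``.
    """
    if n_cross < 0 or n_long < 0:
        raise InvalidConfiguration("donor counts must be non-negative")
    lo, hi = float(age_range[0]), float(age_range[1])
    if not (lo >= 0 and hi > lo):
        raise InvalidConfiguration(f"invalid age_range {age_range}")
    if n_long > 0:
        if visits_per_long < 2:
            raise InvalidConfiguration(
                "longitudinal donors require visits_per_long >= 2"
            )
        if visit_gap_mean <= 0:
            raise InvalidConfiguration("visit_gap_mean must be positive")

    streams = np.random.SeedSequence(seed).spawn(n_cross + n_long)
    donors: list[DonorRecord] = []
    for i in range(n_cross):
        rng = np.random.default_rng(streams[i])
        age = float(rng.uniform(lo, hi))
        donors.append(
            DonorRecord(
                donor_id=f"XS{i + 1:03d}",
                sex="F" if i % 2 == 0 else "M",
                cohort="cross_sectional",
                visits=(("v1", age),),
            )
        )
    span_needed = (visits_per_long - 1) * visit_gap_mean if n_long else 0.0
    for j in range(n_long):
        rng = np.random.default_rng(streams[n_cross + j])
        flo = max(lo, long_first_visit_range[0])
        fhi = min(long_first_visit_range[1], hi - span_needed - 2.0)
        if fhi <= flo:  # narrow design: fall back to whatever fits
            flo, fhi = lo, max(lo + 1.0, hi - span_needed - 2.0)
        age = float(rng.uniform(flo, fhi))
        visits = [("v1", age)]
        for k in range(1, visits_per_long):
            gap = max(1.0, float(rng.normal(visit_gap_mean, 1.0)))
            age = age + gap
            visits.append((f"v{k + 1}", age))
        donors.append(
            DonorRecord(
                donor_id=f"LG{j + 1:03d}",
                sex="F" if j % 2 == 0 else "M",
                cohort="longitudinal",
                visits=tuple(visits),
            )
        )
    return donors


# ---------------------------------------------------------------------------
# count generation
# ---------------------------------------------------------------------------


def _zero_truncated_nb(rng, mean, size_param):
    """Draw zero-truncated NB counts with the given untruncated mean."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    cdf0 = p**size_param
    u = cdf0 + (1.0 - cdf0) * rng.random(mean.shape)
    k = stats.nbinom.ppf(u, size_param, p)
    return np.maximum(k, 1.0).astype(np.int64)


def truncated_nb_mean(mean, size_param):
    """Mean of the zero-truncated NB given the untruncated mean."""
    mean = np.asarray(mean, dtype=float)
    p0 = (size_param / (size_param + mean)) ** size_param
    return mean / (1.0 - p0)


def generate_counts(
    donors: Sequence[DonorRecord],
    gene_specs: Sequence[GeneEffectSpec],
    sim: CellSimSpec,
) -> ad.AnnData:
    """Generate a UMI count matrix (cells x genes) with planted truth.

    Per cell: a subset is drawn from the age-dependent composition, a latent
    ``true_cell_age`` is formed (donor age + subset offset + jitter, floored
    at 0), and each gene is detected with probability
    ``baseline_detect + detect_slope * true_cell_age`` (clamped to [0, 1]);
    detected cells draw a zero-truncated NB count with mean
    ``baseline_mean * (1 + level_slope * true_cell_age)``.

    Returns an :class:`anndata.AnnData` whose ``var`` carries the planted
    gene parameters and whose ``obs`` carries donor metadata, ``total_umi``,
    a simulated ``mito_frac`` (Beta with a 5% contaminated tail) and
    ``true_cell_age``.  Clamping events are counted in ``uns['clamp_log']``.
    """
    if len(donors) == 0 or len(gene_specs) == 0:
        raise ValueError("need at least one donor and one gene")
    subsets = list(sim.subset_composition)
    base = np.array([sim.subset_composition[s][0] for s in subsets])
    comp_slope = np.array([sim.subset_composition[s][1] for s in subsets])
    offsets = np.array(
        [sim.subset_age_offsets.get(s, 0.0) for s in subsets]
    )
    n_genes = len(gene_specs)
    streams = np.random.SeedSequence(sim.seed).spawn(len(donors))

    blocks, obs_rows = [], []
    clamp = {"composition": 0, "detect_prob": 0, "nb_mean": 0}
    for donor, stream in zip(donors, streams):
        rng = np.random.default_rng(stream)
        for visit_id, age in donor.visits:
            n = sim.cells_per_visit
            props = base + comp_slope * age
            if (props < 0).any() or (props > 1).any():
                clamp["composition"] += 1
            props = np.clip(props, 0.0, 1.0)
            props = props / props.sum()
            ks = rng.choice(len(subsets), size=n, p=props)
            cell_age = np.maximum(
                0.0,
                age + offsets[ks] + rng.normal(0.0, sim.cell_age_jitter_sd, n),
            )
            counts = np.zeros((n, n_genes), dtype=np.int64)
            for gi, gs in enumerate(gene_specs):
                p_det = gs.baseline_detect + gs.detect_slope * cell_age
                if (p_det < 0).any() or (p_det > 1).any():
                    clamp["detect_prob"] += int(
                        ((p_det < 0) | (p_det > 1)).sum()
                    )
                p_det = np.clip(p_det, 0.0, 1.0)
                det = rng.random(n) < p_det
                if not det.any():
                    continue
                m = gs.baseline_mean * (1.0 + gs.level_slope * cell_age[det])
                if gs.subset_offsets:
                    mult = np.array(
                        [
                            gs.subset_offsets.get(subsets[k], 1.0)
                            for k in ks[det]
                        ]
                    )
                    m = m * mult
                bad = m <= 0
                if bad.any():
                    clamp["nb_mean"] += int(bad.sum())
                    m = np.where(bad, 0.01, m)
                counts[det, gi] = _zero_truncated_nb(rng, m, gs.dispersion)
            mito = rng.beta(2.0, 30.0, size=n)
            tail = rng.random(n) < 0.05
            mito[tail] = rng.beta(8.0, 12.0, size=int(tail.sum()))
            blocks.append(csr_matrix(counts))
            for i in range(n):
                obs_rows.append(
                    {
                        "cell_id": f"{donor.donor_id}.{visit_id}.{i:04d}",
                        "donor_id": donor.donor_id,
                        "visit_id": visit_id,
                        "age_years": age,
                        "sex": donor.sex,
                        "group_id": donor.group_id,
                        "subset": subsets[ks[i]],
                        "mito_frac": float(mito[i]),
                        "true_cell_age": float(cell_age[i]),
                    }
                )
    if clamp["nb_mean"]:
        logger.warning(
            "clamped %d non-positive NB means to 0.01", clamp["nb_mean"]
        )
    from scipy.sparse import vstack

    X = vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    obs["total_umi"] = np.asarray(X.sum(axis=1)).ravel().astype(np.int64)
    var = pd.DataFrame(
        {
            "mode": [g.mode for g in gene_specs],
            "detect_slope": [g.detect_slope for g in gene_specs],
            "level_slope": [g.level_slope for g in gene_specs],
            "baseline_mean": [g.baseline_mean for g in gene_specs],
            "dispersion": [g.dispersion for g in gene_specs],
            "baseline_detect": [g.baseline_detect for g in gene_specs],
        },
        index=[g.gene_id for g in gene_specs],
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["normalized"] = False
    adata.uns["clamp_log"] = clamp
    return adata


def generate_planted_lognorm(
    n_cells: int,
    gene_slopes: Mapping[str, float],
    noise_sd: float = 0.5,
    intercept: float = 1.0,
    sex_coef: float = 0.0,
    group_offsets: Mapping[str, float] | None = None,
    age_range: tuple = (0.0, 90.0),
    seed: int = 0,
) -> ad.AnnData:
    """Matrix whose log2-normalized layer follows an exact linear age model.

    Each gene's log2-normalized expression is drawn as
    ``intercept + slope * age + sex_coef * sex + group_offset + N(0, sd)``
    — a calibration harness for the per-gene age regression where the
    planted fixed-effect slope is known in the model's own units.  The raw
    layer is all-ones (every gene detected in every cell).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = list(gene_slopes)
    ages = rng.uniform(age_range[0], age_range[1], size=n_cells)
    sex_num = (rng.random(n_cells) < 0.5).astype(float)
    if group_offsets is None:
        groups = np.full(n_cells, CROSS_SECTIONAL_GROUP, dtype=object)
        off = np.zeros(n_cells)
    else:
        keys = list(group_offsets)
        gi = rng.integers(0, len(keys), size=n_cells)
        groups = np.array([keys[k] for k in gi], dtype=object)
        off = np.array([group_offsets[keys[k]] for k in gi])
    slopes = np.array([gene_slopes[g] for g in genes])
    signal = (
        intercept
        + ages[:, None] * slopes[None, :]
        + sex_coef * sex_num[:, None]
        + off[:, None]
    )
    layer = signal + rng.normal(0.0, noise_sd, size=(n_cells, len(genes)))
    obs = pd.DataFrame(
        {
            "donor_id": groups,
            "visit_id": "v1",
            "age_years": ages,
            "sex": np.where(sex_num > 0, "M", "F"),
            "group_id": groups,
            "subset": "Na",
            "total_umi": len(genes),
            "mito_frac": 0.05,
        },
        index=[f"cell{i:05d}" for i in range(n_cells)],
    )
    adata = ad.AnnData(
        X=csr_matrix(np.ones((n_cells, len(genes)), dtype=np.int64)),
        obs=obs,
        var=pd.DataFrame({"planted_co": slopes}, index=genes),
    )
    adata.layers["log2norm"] = layer
    adata.uns["normalized"] = True
    return adata


# ---------------------------------------------------------------------------
# planted-effect calibration helpers
# ---------------------------------------------------------------------------


def detect_slope_for_span(span: float, age_span: float = 90.0) -> float:
    """Detection-probability slope per year giving ``span`` over the cohort."""
    return span / age_span


def level_slope_for_relative_span(
    target_rel_span: float,
    baseline_mean: float,
    dispersion: float,
    scale: float = 1e4,
    expected_total_umi: float = 1200.0,
    age_range: tuple = (0.0, 90.0),
) -> float:
    """Level slope whose log2-normalized span is a given fraction of the mean.

    Solves for the per-year relative change in the positive-cell NB mean such
    that the expected log2-normalized positive-cell expression changes by
    ``target_rel_span`` (as a fraction of its mid-cohort value) across the
    cohort age range.  Signed: negative targets give declining genes.
    """
    lo, hi = age_range
    mid = 0.5 * (lo + hi)

    def expected_expr(age, ls):
        m = baseline_mean * (1.0 + ls * age)
        if m <= 0:
            return np.nan
        mt = float(truncated_nb_mean(m, dispersion))
        return np.log2(1.0 + mt * scale / expected_total_umi)

    def gap(ls):
        e_lo, e_hi = expected_expr(lo, ls), expected_expr(hi, ls)
        e_mid = expected_expr(mid, ls)
        return (e_hi - e_lo) / e_mid - target_rel_span

    bound = 0.95 / max(hi, 1.0)  # keep NB mean positive over the range
    return float(optimize.brentq(gap, -bound, bound))


# ---------------------------------------------------------------------------
# variant evidence
# ---------------------------------------------------------------------------


def generate_variant_evidence(
    adata: ad.AnnData,
    burden_model: BurdenModel,
    error_rate: float = 0.0,
    seed: int = 0,
    tlod_fail_frac: float = 0.05,
    depth_fail_frac: float = 0.05,
):
    """Generate per-UMI variant evidence with planted mutation burden.

    True mutations are drawn per cell as Poisson with the
    :class:`BurdenModel` log-linear rate; their UMIs carry consistently alt
    reads (>=3 reads, alt fraction near 1) so they survive consensus
    filtering, apart from configurable fractions planted to fail the TLOD
    and exome-depth gates.  Sequencing-error artifacts (rate
    ``error_rate`` per cell UMI) carry either <3 reads or a minority alt
    fraction, so the consensus rule removes them.

    Adds ``cell_coverage``, ``donor_exome_coverage``, ``true_mutation_count``
    and ``burden_lambda`` columns to ``adata.obs``.  Returns a list of
    :class:`tcellclock.mutations.VariantEvidence`.
    """
    from .mutations import VariantEvidence

    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    if adata.n_obs == 0:
        return []
    # covariate generation uses its own sub-stream, so evidence draws are
    # identical whether or not the covariate columns already exist
    cov_ss, ev_ss = np.random.SeedSequence((seed, 0xC0FFEE)).spawn(2)
    rng_cov = np.random.default_rng(cov_ss)
    rng = np.random.default_rng(ev_ss)
    obs = adata.obs
    total_umi = obs["total_umi"].to_numpy(dtype=float)

    if "cell_coverage" not in obs:
        adata.obs["cell_coverage"] = total_umi * 50.0 * rng_cov.lognormal(
            0.0, 0.3, size=adata.n_obs
        )
    if "donor_exome_coverage" not in obs:
        donor_cov = {
            d: float(rng_cov.lognormal(np.log(60.0), 0.2))
            for d in obs["donor_id"].unique()
        }
        adata.obs["donor_exome_coverage"] = (
            obs["donor_id"].map(donor_cov).astype(float)
        )
    obs = adata.obs
    cell_cov = obs["cell_coverage"].to_numpy(dtype=float)
    exo_cov = obs["donor_exome_coverage"].to_numpy(dtype=float)
    cell_age = (
        obs["true_cell_age"].to_numpy(dtype=float)
        if "true_cell_age" in obs
        else obs["age_years"].to_numpy(dtype=float)
    )

    def zlog(x):
        lx = np.log(np.maximum(x, 1e-12))
        return lx - lx.mean()

    lam = burden_model.rate0 * np.exp(
        burden_model.coef_log_umi * zlog(total_umi)
        + burden_model.coef_log_cell_cov * zlog(cell_cov)
        + burden_model.coef_log_exome_cov * zlog(exo_cov)
        + burden_model.coef_cell_age * cell_age
    )
    true_n = rng.poisson(lam)
    adata.obs["burden_lambda"] = lam
    adata.obs["true_mutation_count"] = true_n

    evidence = []
    umi_counter = 0

    def new_site():
        chrom = f"chr{rng.integers(1, 23)}"
        pos = int(rng.integers(1, 50_000_001))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        return chrom, pos, str(ref), str(alt)

    for ci, cell_id in enumerate(obs.index):
        donor = obs["donor_id"].iloc[ci]
        for _ in range(int(true_n[ci])):
            chrom, pos, ref, alt = new_site()
            n_umi = 1 + int(rng.poisson(0.7))
            support = []
            for _ in range(n_umi):
                total_reads = 3 + int(rng.poisson(3.0))
                alt_reads = max(1, int(rng.binomial(total_reads, 0.97)))
                umi_counter += 1
                support.append((f"UMI{umi_counter:07d}", alt_reads, total_reads))
            tlod = (
                float(rng.uniform(0.0, 5.3))
                if rng.random() < tlod_fail_frac
                else 5.31 + float(rng.exponential(8.0))
            )
            depth = (
                int(rng.integers(1, 11))
                if rng.random() < depth_fail_frac
                else 11 + int(rng.poisson(40.0))
            )
            evidence.append(
                VariantEvidence(
                    cell_id=cell_id,
                    donor_id=donor,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    tlod=tlod,
                    exome_depth=depth,
                    umi_support=tuple(support),
                )
            )
        if error_rate > 0:
            n_art = int(rng.poisson(error_rate * total_umi[ci]))
            for _ in range(n_art):
                chrom, pos, ref, alt = new_site()
                if rng.random() < 0.5:  # too few reads in the UMI
                    total = int(rng.integers(1, 3))
                    alt_reads = total
                else:  # minority alt fraction
                    total = int(rng.integers(6, 11))
                    alt_reads = max(1, int(0.3 * total))
                umi_counter += 1
                evidence.append(
                    VariantEvidence(
                        cell_id=cell_id,
                        donor_id=donor,
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        tlod=float(rng.uniform(0.0, 8.0)),
                        exome_depth=11 + int(rng.poisson(40.0)),
                        umi_support=((f"UMI{umi_counter:07d}", alt_reads, total),),
                    )
                )
    return evidence
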