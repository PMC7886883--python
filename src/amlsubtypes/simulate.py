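"""Synthetic multi-cohort data with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
several cohorts of negative-binomial RNA-seq counts with two planted
expression subtypes (primitive / committed), additive per-(cohort, gene)
log-scale batch shifts that keep cohorts unmergeable without the
centroid-network step, a weakly subtype-correlated mutation flag, subtype-
dependent exponential survival, and a cell-line panel whose Hill
dose-response curves shift for a few active drugs in primitive-like lines.
Everything is deterministic given the seed, and the returned truth object
records every planted quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import DoseResponseRecord, SampleMetadata
from .matrix import ExpressionMatrix

#: default stem-signature flag name; an FLT3-ITD-like co-mutation
MUTATION_FLAG = "FLT3_ITD"
#: marginal frequency of the mutation flag (FLT3-ITD-like)
MUTATION_PREVALENCE = 0.40
#: committed-group median survival used to anchor the baseline hazard (days)
BASELINE_MEDIAN_DAYS = 730.0


@dataclass
class SimulationConfig:
    """Planted-scenario parameters.

    The defaults define the study conditions every recovery test runs
    under: five cohorts of 60-100 samples, 2000 genes of which 10% are
    subtype-informative at one log2 unit (half of them the stem signature,
    up in primitive), negative-binomial dispersion 0.2, batch shifts of
    SD 0.3 log2 units, a mutation flag targeting MCC 0.32 with the
    subtype, a 60-line cell panel with 3 of 20 drugs shifting AUC_d by
    -0.25 in primitive-like lines, and a subtype hazard ratio of 2.2
    with 20% censoring.
    """

    n_cohorts: int = 5
    samples_per_cohort: tuple = (60, 100)   # inclusive range, drawn per cohort
    n_genes: int = 2000
    frac_signature: float = 0.10
    lfc_signature: float = 1.0              # log2 units, primitive vs committed
    nb_dispersion: float = 0.2
    batch_sd: float = 0.3                   # log2 units per (cohort, gene)
    prevalence_primitive: float = 0.45
    mutation_mcc_target: float = 0.32
    n_cell_lines: int = 60
    n_drugs: int = 20
    n_active_drugs: int = 3
    drug_effect: float = -0.25              # AUC_d shift in primitive lines
    ec50_range: tuple = (0.05, 5.0)         # µM, log-uniform
    hill_range: tuple = (0.7, 2.5)
    dose_range: tuple = (0.001, 10.0)       # µM, 10 log-spaced doses
    n_doses: int = 10
    n_replicates: int = 3
    viability_noise_sd: float = 0.05
    hr_subtype: float = 2.2
    censor_frac: float = 0.2

    def __post_init__(self) -> None:
        for name in ("frac_signature", "prevalence_primitive", "censor_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_active_drugs > self.n_drugs:
            raise ValueError("n_active_drugs cannot exceed n_drugs")


@dataclass
class SyntheticTruth:
    """Every planted quantity, sufficient to check any stage without
    re-simulation."""

    subtype: dict                      # sample_id -> primitive/committed
    stem_up_genes: list
    committed_up_genes: list
    true_lfc: dict                     # gene_id -> planted log2 fold change
    batch_shifts: dict                 # cohort_id -> {gene_id: shift}
    baseline_log2_mean: dict           # gene_id -> baseline
    mutation_rates: dict               # {"p_primitive":..., "p_committed":...}
    drug_effects: dict = field(default_factory=dict)   # drug_id -> AUC_d shift
    cell_line_subtype: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)       # hazards & censoring
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _mutation_rates(pi: float, target_mcc: float, q: float = MUTATION_PREVALENCE):
    """Class-conditional flag rates hitting the target phi coefficient.

    For binary subtype S ~ Bernoulli(pi) and flag M with marginal q,
    phi = pi (p1 - q) / sqrt(pi (1-pi) q (1-q)).
    """
    p1 = q + target_mcc * np.sqrt(pi * (1 - pi) * q * (1 - q)) / pi
    p0 = (q - pi * p1) / (1 - pi)
    if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
        raise ValueError(
            f"MCC target {target_mcc} infeasible at prevalence {pi} "
            f"with flag frequency {q}")
    return float(p1), float(p0)


def _nb_counts(log2_mean: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    mu = 2.0 ** log2_mean
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def simulate_cohorts(cfg: SimulationConfig | None = None, seed: int = 0):
    """Plant two subtypes across ``n_cohorts`` count matrices.

    Returns (list of raw-count ExpressionMatrix, list of SampleMetadata,
    SyntheticTruth). Survival fields and the mutation flag are filled in
    the metadata.
    """
    cfg = cfg or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    base = rng.uniform(3.0, 10.0, size=cfg.n_genes)
    n_sig = int(round(cfg.frac_signature * cfg.n_genes))
    sig_idx = rng.choice(cfg.n_genes, size=n_sig, replace=False)
    stem_idx = np.sort(sig_idx[: n_sig // 2])
    comm_idx = np.sort(sig_idx[n_sig // 2:])
    effect = np.zeros(cfg.n_genes)
    effect[stem_idx] = cfg.lfc_signature      # up in primitive
    effect[comm_idx] = -cfg.lfc_signature     # up in committed

    p1, p0 = _mutation_rates(cfg.prevalence_primitive, cfg.mutation_mcc_target)

    matrices: list[ExpressionMatrix] = []
    metadata: list[SampleMetadata] = []
    subtype_by_sample: dict = {}
    batch_by_cohort: dict = {}
    lo, hi = cfg.samples_per_cohort
    for c in range(cfg.n_cohorts):
        cohort_id = f"cohort{c + 1}"
        n = int(rng.integers(lo, hi + 1))
        primitive = rng.random(n) < cfg.prevalence_primitive
        batch = rng.normal(0.0, cfg.batch_sd, size=cfg.n_genes)
        batch_by_cohort[cohort_id] = batch
        sample_ids = [f"{cohort_id}_S{i:03d}" for i in range(n)]
        # log2 mean per (gene, sample): baseline + batch + half-effect by side
        signs = np.where(primitive, 0.5, -0.5)
        log2_mean = (base + batch)[:, None] + effect[:, None] * signs[None, :]
        counts = _nb_counts(log2_mean, cfg.nb_dispersion, rng)
        matrices.append(ExpressionMatrix(
            cohort_id, pd.DataFrame(counts, index=genes, columns=sample_ids),
            "raw_counts"))
        mut = np.where(primitive, rng.random(n) < p1, rng.random(n) < p0)
        for sid, prim, m in zip(sample_ids, primitive, mut):
            subtype_by_sample[sid] = "primitive" if prim else "committed"
            metadata.append(SampleMetadata(
                sample_id=sid, cohort_id=cohort_id,
                mutation_flags={MUTATION_FLAG: int(m)}))

    truth = SyntheticTruth(
        subtype=subtype_by_sample,
        stem_up_genes=[genes[i] for i in stem_idx],
        committed_up_genes=[genes[i] for i in comm_idx],
        true_lfc={g: float(e) for g, e in zip(genes, effect)},
        batch_shifts={c: {g: float(b) for g, b in zip(genes, arr)}
                      for c, arr in batch_by_cohort.items()},
        baseline_log2_mean={g: float(b) for g, b in zip(genes, base)},
        mutation_rates={"p_primitive": p1, "p_committed": p0,
                        "marginal": MUTATION_PREVALENCE},
        seed=seed,
    )

    # survival on the pooled samples, reproducibly derived from the master seed
    surv_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    subtype_series = pd.Series(subtype_by_sample)
    surv = simulate_survival(subtype_series, cfg, surv_seed)
    truth.survival = {"h0_per_day": float(np.log(2) / BASELINE_MEDIAN_DAYS),
                      "hr_subtype": cfg.hr_subtype,
                      "censor_frac": cfg.censor_frac, "seed": surv_seed}
    by_sample = {r.sample_id: r for r in metadata}
    for sid, row in surv.iterrows():
        by_sample[sid].os_time = float(row["time"])
        by_sample[sid].os_event = int(row["event"])
    return matrices, metadata, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _censor_horizon(h0: float, h1: float, pi: float, target: float) -> float:
    """Upper end of the uniform censoring window giving the target
    censoring fraction for the exponential mixture."""

    def p_cens(c):
        def one(h):
            return (1.0 - np.exp(-h * c)) / (h * c)
        return pi * one(h1) + (1 - pi) * one(h0) - target

    return brentq(p_cens, 1e-6, 1e9)


def simulate_survival(subtypes: pd.Series, cfg: SimulationConfig | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Exponential survival with subtype hazard ratio and uniform censoring.

    ``subtypes``: sample -> primitive/committed. Committed samples have
    baseline hazard h0 (median 2 years); primitive h0 * hr_subtype.
    Returns a frame indexed by sample with ``time`` (days) and ``event``.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    h0 = np.log(2) / BASELINE_MEDIAN_DAYS
    h1 = h0 * cfg.hr_subtype
    prim = (subtypes == "primitive").to_numpy()
    hz = np.where(prim, h1, h0)
    t_event = rng.exponential(1.0 / hz)
    if cfg.censor_frac <= 0:
        return pd.DataFrame({"time": t_event, "event": 1}, index=subtypes.index)
    c_max = _censor_horizon(h0, h1, float(prim.mean()), cfg.censor_frac)
    t_cens = rng.uniform(0.0, c_max, size=len(subtypes))
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": observed, "event": event}, index=subtypes.index)


# ---------------------------------------------------------------------------
# cell-line panel
# ---------------------------------------------------------------------------

def _auc_closed_form(u0: float, h: float, u_min: float, u_max: float) -> float:
    width = u_max - u_min
    a = h * np.log(10.0)
    integral = width - (np.logaddexp(0.0, a * (u_max - u0))
                        - np.logaddexp(0.0, a * (u_min - u0))) / a
    return float(integral / width)


def _shift_ec50_for_auc(u0: float, h: float, u_min: float, u_max: float,
                        delta_auc: float) -> float:
    """log10 EC50 whose AUC_d equals auc(u0) + delta (clipped to range)."""
    target = _auc_closed_form(u0, h, u_min, u_max) + delta_auc
    lo, hi = u_min - 6.0, u_max + 6.0
    target = float(np.clip(target,
                           _auc_closed_form(lo, h, u_min, u_max) + 1e-9,
                           _auc_closed_form(hi, h, u_min, u_max) - 1e-9))
    return brentq(lambda v: _auc_closed_form(v, h, u_min, u_max) - target, lo, hi)


def simulate_cellline_panel(truth: SyntheticTruth,
                            cfg: SimulationConfig | None = None, seed: int = 0):
    """Cell-line expression plus a planted drug screen.

    Expression comes from the same two-subtype count model with its own
    batch shift. For each (line, drug) an EC50 is drawn log-uniformly;
    for active drugs the EC50 of primitive-like lines is moved so the
    line's expected AUC_d changes by exactly ``drug_effect``. Viabilities
    are Hill-curve values plus Gaussian noise at 10 log-spaced doses in
    3 replicates. Returns (ExpressionMatrix, records, subtype Series).
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    genes = list(truth.baseline_log2_mean)
    base = np.array([truth.baseline_log2_mean[g] for g in genes])
    effect = np.array([truth.true_lfc[g] for g in genes])

    n = cfg.n_cell_lines
    line_ids = [f"CL{i:03d}" for i in range(n)]
    primitive = rng.random(n) < cfg.prevalence_primitive
    batch = rng.normal(0.0, cfg.batch_sd, size=len(genes))
    signs = np.where(primitive, 0.5, -0.5)
    log2_mean = (base + batch)[:, None] + effect[:, None] * signs[None, :]
    counts = _nb_counts(log2_mean, cfg.nb_dispersion, rng)
    expr = ExpressionMatrix("celllines",
                            pd.DataFrame(counts, index=genes, columns=line_ids),
                            "raw_counts")

    drug_ids = [f"drug{d + 1:02d}" for d in range(cfg.n_drugs)]
    active = set(rng.choice(cfg.n_drugs, size=cfg.n_active_drugs, replace=False))
    truth.drug_effects = {d: (cfg.drug_effect if i in active else 0.0)
                          for i, d in enumerate(drug_ids)}
    truth.cell_line_subtype = {
        lid: ("primitive" if p else "committed")
        for lid, p in zip(line_ids, primitive)}

    u_min, u_max = np.log10(cfg.dose_range[0]), np.log10(cfg.dose_range[1])
    doses = np.logspace(u_min, u_max, cfg.n_doses)
    records: list[DoseResponseRecord] = []
    for i, drug in enumerate(drug_ids):
        is_active = i in active
        for lid, prim in zip(line_ids, primitive):
            u0 = rng.uniform(np.log10(cfg.ec50_range[0]),
                             np.log10(cfg.ec50_range[1]))
            h = rng.uniform(*cfg.hill_range)
            if is_active and prim:
                u0 = _shift_ec50_for_auc(u0, h, u_min, u_max, cfg.drug_effect)
            from scipy.special import expit
            clean = expit(-h * np.log(10.0) * (np.log10(doses) - u0))
            for rep in range(1, cfg.n_replicates + 1):
                noisy = np.maximum(
                    clean + rng.normal(0.0, cfg.viability_noise_sd, cfg.n_doses),
                    0.0)
                for x, v in zip(doses, noisy):
                    records.append(DoseResponseRecord(
                        sample_id=lid, drug_id=drug, concentration=float(x),
                        viability=float(v), replicate=rep))
    subtype = pd.Series(truth.cell_line_subtype, name="subtype").loc[line_ids]
    return expr, records, subtype
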