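"""Two-stage classification: unprimed fits -> species priors -> adapted refits.

Stage 1 fits every fish's 12-parameter model with only the Beta transition
prior. Data-rich fits (long, converged, both states visited) are selected and
their fitted state means summarised into species-level Gaussian priors
N(m_jd, delta_jd) — four per species, one per state x dimension. Stage 2
refits the remaining (data-poor) fish with those priors multiplied into the
likelihood, anchoring state identity so that "resident" means the same thing
in every fish. Stage-1 fits of the selected fish are kept as-is, so the
priors are never applied to the fish they were built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .hmm import (
    MIGRATING,
    RESIDENT,
    FitConfig,
    FittedModel,
    HMMParameters,
    MeanPriors,
    TransitionPrior,
    fit_map,
)
from .io import MovementPath, PipelineError, UsageError


@dataclass
class SelectionCriteria:
    """Data-rich selection rule: converged, long enough, both states used."""

    min_T: int = 150
    min_state_fraction: float = 0.10
    require_converged: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_state_fraction < 0.5:
            raise UsageError("min_state_fraction must lie in (0, 0.5)")


class MeanPriorSet:
    """Per-species movement-parameter priors, serialisable to YAML."""

    def __init__(self, priors: dict[str, MeanPriors]):
        self.priors = dict(priors)

    def for_species(self, species: str) -> MeanPriors:
        if species not in self.priors:
            raise UsageError(f"no movement-parameter priors for species {species!r}")
        return self.priors[species]

    def scaled(self, factor: float) -> "MeanPriorSet":
        return MeanPriorSet({s: p.scaled(factor) for s, p in self.priors.items()})

    def species(self) -> list[str]:
        return sorted(self.priors)

    def to_yaml(self, path) -> None:
        doc = {
            s: {"m": p.m.tolist(), "delta": p.delta.tolist()}
            for s, p in self.priors.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "MeanPriorSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            {s: MeanPriors(np.array(d["m"]), np.array(d["delta"])) for s, d in doc.items()}
        )


def select_data_rich(
    fits: list[FittedModel], c: SelectionCriteria | None = None
) -> tuple[list[FittedModel], pd.DataFrame]:
    """Split fits into the data-rich subset, with a per-fish pass/fail report."""
    c = c or SelectionCriteria()
    rows = []
    selected = []
    for f in fits:
        frac_r = f.state_fraction(RESIDENT)
        frac_m = f.state_fraction(MIGRATING)
        ok_conv = f.converged or not c.require_converged
        ok_len = f.T >= c.min_T
        ok_occ = min(frac_r, frac_m) >= c.min_state_fraction
        passed = ok_conv and ok_len and ok_occ
        rows.append(
            {
                "fish_id": f.path.fish_id,
                "species": f.path.species,
                "T": f.T,
                "converged": f.converged,
                "frac_resident": frac_r,
                "passed": passed,
            }
        )
        if passed:
            selected.append(f)
    report = pd.DataFrame(rows)
    if not selected:
        raise PipelineError(
            "no fits satisfy the data-rich criteria; relax min_T / "
            "min_state_fraction or check convergence"
        )
    return selected, report


def build_mean_priors(selected: list[FittedModel], species: str) -> MeanPriors:
    """Summarise selected fits' state means into the species prior.

    m_jd is the across-fish mean of the fitted mu_jd, delta_jd the unbiased
    across-fish variance, floored at 1e-4 so a unanimous subset still yields a
    proper (if tight) prior.
    """
    mus = np.array([f.params.mu for f in selected if f.path.species == species])
    if mus.shape[0] < 2:
        raise ValueError(f"need >= 2 selected fits for species {species!r}")
    m = mus.mean(axis=0)
    delta = np.maximum(mus.var(axis=0, ddof=1), 1e-4)
    return MeanPriors(m, delta)


def fit_adapted(
    path: MovementPath,
    tp: TransitionPrior,
    mp: MeanPriorSet | MeanPriors,
    cfg: FitConfig | None = None,
) -> FittedModel:
    """Fit with the movement-parameter priors active (prior-anchored labels)."""
    priors = mp.for_species(path.species) if isinstance(mp, MeanPriorSet) else mp
    return fit_map(path, tp, priors, cfg)


@dataclass
class TwoStageResult:
    fits: dict[str, FittedModel]
    priors: MeanPriorSet
    report: pd.DataFrame
    selected_ids: list[str] = field(default_factory=list)


def _fish_seed(base_seed: int, fish_id: str) -> int:
    # stable per-fish stream regardless of cohort order
    import zlib

    return (int(base_seed) * 100_003 + zlib.crc32(fish_id.encode())) % (2**31 - 1)


def run_two_stage(
    cohort: list[MovementPath],
    tp: TransitionPrior | None = None,
    criteria: SelectionCriteria | None = None,
    cfg: FitConfig | None = None,
) -> TwoStageResult:
    """Run the full two-stage classification over a cohort.

    Returns one decoded fit per fish (stage 1 for the selected data-rich
    subset, stage 2 for everyone else), the per-species priors, and a per-fish
    report (stage, convergence, length, state occupancy).
    """
    tp = tp or TransitionPrior()
    criteria = criteria or SelectionCriteria()
    cfg = cfg or FitConfig()
    by_species: dict[str, int] = {}
    for p in cohort:
        by_species[p.species] = by_species.get(p.species, 0) + 1
    for sp, n in by_species.items():
        if n < 2:
            raise PipelineError(f"species {sp!r} has {n} fish; need >= 2")

    stage1: dict[str, FittedModel] = {}
    for path in cohort:
        c = FitConfig(
            n_restarts=cfg.n_restarts,
            seed=_fish_seed(cfg.seed, path.fish_id),
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            sigma_floor=cfg.sigma_floor,
        )
        stage1[path.fish_id] = fit_map(path, tp, None, c)

    selected, report = select_data_rich(list(stage1.values()), criteria)
    selected_ids = [f.path.fish_id for f in selected]
    priors = MeanPriorSet(
        {
            sp: build_mean_priors(selected, sp)
            for sp in sorted(by_species)
            if sum(f.path.species == sp for f in selected) >= 2
        }
    )
    missing = [sp for sp in by_species if sp not in priors.priors]
    if missing:
        raise PipelineError(
            f"species {missing} have < 2 data-rich fits; cannot build priors"
        )

    fits: dict[str, FittedModel] = {}
    stages = {}
    for path in cohort:
        if path.fish_id in selected_ids:
            fits[path.fish_id] = stage1[path.fish_id]
            stages[path.fish_id] = 1
        else:
            c = FitConfig(
                n_restarts=cfg.n_restarts,
                seed=_fish_seed(cfg.seed + 1, path.fish_id),
                max_iter=cfg.max_iter,
                tol=cfg.tol,
                sigma_floor=cfg.sigma_floor,
            )
            fits[path.fish_id] = fit_adapted(path, tp, priors, c)
            stages[path.fish_id] = 2

    report = report.assign(stage=report["fish_id"].map(stages))
    return TwoStageResult(fits, priors, report, selected_ids)


def is_label_flipped(params, priors: MeanPriors) -> bool:
    """True when a fit's state means are swapped relative to the species prior.

    Compares the total prior-standardised squared distance of the fitted
    means under the direct assignment (mu_R -> m_R, mu_M -> m_M) against the
    swapped one; a flip means the swapped assignment fits better. This is the
    operational meaning of consistent state identity: "resident" in one fish
    is the same behavioural mode as in every other.
    """
    z_direct = float(np.sum((params.mu - priors.m) ** 2 / priors.delta))
    z_swapped = float(np.sum((params.mu[::-1] - priors.m) ** 2 / priors.delta))
    return z_swapped < z_direct


# ---------------------------------------------------------------------------
# Parameter serialisation / re-decoding (re-runnable pipeline stages)
# ---------------------------------------------------------------------------

_PARAM_COLS = [
    "fish_id", "gamma_rr", "gamma_mm",
    "mu_rh", "mu_rv", "mu_mh", "mu_mv",
    "sigma_rh", "sigma_rv", "sigma_mh", "sigma_mv",
    "rho_r", "rho_m", "log_posterior", "converged",
]


def write_params_csv(fits: dict[str, FittedModel], path) -> None:
    rows = []
    for fid in sorted(fits):
        f = fits[fid]
        p = f.params
        rows.append(
            [fid, p.gamma_rr, p.gamma_mm, *p.mu.ravel(), *p.sigma.ravel(),
             *p.rho, f.log_posterior, f.converged]
        )
    pd.DataFrame(rows, columns=_PARAM_COLS).to_csv(path, index=False, float_format="%.10g")


def read_params_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"fish_id": str})
    missing = [c for c in _PARAM_COLS if c not in df.columns]
    if missing:
        raise UsageError(f"{path}: missing columns {missing}")
    return df


def decode_with_params(paths: list[MovementPath], params: pd.DataFrame) -> dict[str, FittedModel]:
    """Rebuild decoded fits (smoothing + allocation) from stored parameters."""
    from .hmm import allocate_states, smooth_states

    by_id = params.set_index("fish_id")
    fits = {}
    for path in paths:
        if path.fish_id not in by_id.index:
            continue
        r = by_id.loc[path.fish_id]
        p = HMMParameters(
            float(r["gamma_rr"]), float(r["gamma_mm"]),
            np.array([[r["mu_rh"], r["mu_rv"]], [r["mu_mh"], r["mu_mv"]]], float),
            np.array([[r["sigma_rh"], r["sigma_rv"]], [r["sigma_mh"], r["sigma_mv"]]], float),
            np.array([r["rho_r"], r["rho_m"]], float),
        )
        sm = smooth_states(path, p)
        states, unc = allocate_states(sm)
        fits[path.fish_id] = FittedModel(
            path, p, float(r["log_posterior"]), bool(r["converged"]),
            smoothed=sm, states=states, uncertain=unc,
        )
    return fits
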