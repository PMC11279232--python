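"""Ground-truth-annotated synthetic plate experiments.

Generates a complete experiment bundle — plate layouts, per-timepoint
colony quantification tables, inhibition-halo scores and the underlying
truth — with the statistical structure the pipeline assumes:

* each isolate grows along a three-parameter Gompertz log2-biomass curve;
* spots are measured on a "daytime" imaging grid (every 2 h for part of
  each of four days, 20 timepoints) with additive Gaussian replicate noise
  and optional per-spot-timepoint dropout;
* plates carry a multiplicative offset on the asymptote (plate-to-plate
  variation that stays within the Gompertz family);
* pair spots follow the dominant individual's curve with the asymptote
  rescaled so the pair's true integrated fitness lands where its assigned
  ecological class demands (beyond +-delta for cooperation/competition,
  within a small jitter of the dominant individual for neutral), using the
  fact that the Gompertz AUC is linear in the asymptote;
* halo phenotypes come from per-isolate antifungal flags with configurable
  pairwise suppression and induction.

Observed size and opacity are back-computed from biomass with an even
split in log space (size = opacity = 2**(biomass/2)), so that
size x opacity = 2**biomass; only the product matters downstream.

All randomness flows from one seeded generator; the same config and seed
reproduce a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import plate_io
from .fitness import gompertz_auc
from .growth_fitting import gompertz
from .interaction_scoring import classify_functional
from .plate_io import PlateLayout, QuantTable, position_label

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "SimulationConfig",
    "SimulatedExperiment",
    "expected_msd",
    "simulate_experiment",
]

#: every 2 h during a 14-h imaging day, capped at 20 usable timepoints
#: (0-14 h, 24-38 h, 48-54 h) — keeps the growth transition of every curve
#: sampled rather than lost in an overnight gap
DEFAULT_TIMEPOINTS = tuple(
    float(day * 24 + h) for day in range(4) for h in range(0, 15, 2)
)[:20]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic plate experiment.

    ``effect_delta_msd`` expresses the injected pair effect in multiples of
    the expected replicate-noise scale (see :func:`expected_msd`); it must
    be at least 2 whenever non-neutral pairs are requested, otherwise the
    injected classes would be unrecoverable by construction.
    """

    seed: int = 0
    n_isolates: int = 384
    media: tuple[str, ...] = ("LM17",)
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    # defaults keep every curve saturating inside the imaging window so the
    # asymptote (and hence IF) is identifiable from the sampled grid
    A_range: tuple[float, float] = (8.0, 12.0)
    k_range: tuple[float, float] = (0.1, 0.25)
    ti_range: tuple[float, float] = (10.0, 24.0)
    noise_sigma: float = 0.05
    plate_offset_sigma: float = 0.0
    frac_cooperative: float = 0.1
    frac_competitive: float = 0.1
    effect_delta_msd: float = 6.0
    neutral_jitter_msd: float = 0.5
    antifungal_prevalence: float = 0.05
    targets: tuple[str, ...] = plate_io.TARGET_YEASTS
    p_suppression: float = 0.3
    p_induction: float = 0.02
    dropout_p: float = 0.0
    t_max: float = 72.0

    def validate(self) -> None:
        for name in (
            "frac_cooperative",
            "frac_competitive",
            "antifungal_prevalence",
            "p_suppression",
            "p_induction",
            "dropout_p",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_cooperative + self.frac_competitive > 1.0:
            raise ValueError("class fractions sum to more than 1")
        if self.n_isolates % 4 != 0 or not 4 <= self.n_isolates <= 384:
            raise ValueError("n_isolates must be a multiple of 4 in [4, 384]")
        if self.noise_sigma < 0 or self.plate_offset_sigma < 0:
            raise ValueError("noise scales must be non-negative")
        if len(self.timepoints) < 5:
            raise ValueError("need at least 5 timepoints")
        if (
            self.frac_cooperative + self.frac_competitive > 0
            and self.effect_delta_msd < 2.0
        ):
            raise ValueError(
                "effect_delta_msd must be >= 2 when cooperative/competitive "
                "pairs are requested (the classification threshold is 2 x MSD)"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for key in ("media", "timepoints", "targets"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        for key in ("A_range", "k_range", "ti_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)


def _gompertz_jacobian(t: np.ndarray, a: float, k: float, ti: float) -> np.ndarray:
    """d gompertz / d (A, k, t_i), shape (len(t), 3)."""
    u = np.exp(-k * (t - ti))
    core = np.exp(-u)
    return np.column_stack((core, a * core * u * (t - ti), -a * core * u * k))


def expected_msd(
    config: SimulationConfig, n_draws: int = 1000, seed: int | None = None
) -> float:
    """Monte-Carlo estimate of the replicate-IF noise scale implied by sigma.

    The pipeline's IF is the AUC of a least-squares Gompertz fit, so the
    per-replicate IF noise is propagated through the fit by the delta
    method: with Jacobian ``J`` of the curve on the imaging grid and
    ``g = dAUC/d(A, k, t_i)``, the IF standard deviation of one replicate
    is ``sigma * sqrt(g' (J'J)^-1 g)``.  For each draw a curve is sampled
    from the config's parameter distributions, four replicate IF values are
    drawn at that scale, and their sample SD recorded; the estimate is the
    median SD over draws.  This is the scale used to calibrate injected
    pair effects.
    """
    if config.noise_sigma == 0:
        return 0.0
    rng = np.random.default_rng(
        config.seed + 20_240_710 if seed is None else seed
    )
    t = np.asarray(config.timepoints, dtype=float)
    t_dense = np.linspace(0.0, config.t_max, 721)
    sds = np.empty(n_draws)
    for i in range(n_draws):
        a = rng.uniform(*config.A_range)
        k = rng.uniform(*config.k_range)
        ti = rng.uniform(*config.ti_range)
        jac = _gompertz_jacobian(t, a, k, ti)
        cov = np.linalg.pinv(jac.T @ jac) * config.noise_sigma**2
        g = np.trapezoid(_gompertz_jacobian(t_dense, a, k, ti), t_dense, axis=0)
        sigma_if = float(np.sqrt(max(g @ cov @ g, 0.0)))
        reps = rng.normal(0.0, sigma_if, size=4)
        sds[i] = np.std(reps, ddof=1)
    return float(np.median(sds))


@dataclass
class SimulatedExperiment:
    """In-memory simulation result plus its ground truth."""

    config: SimulationConfig
    layouts: list[PlateLayout]
    quant_tables: list[QuantTable]
    halos: pd.DataFrame
    truth_isolates: pd.DataFrame
    truth_pairs: pd.DataFrame
    expected_msd: float

    def write_bundle(self, out_dir: str | Path) -> Path:
        """Write the bundle (layouts, quant tables, halos, truth, config)."""
        out = Path(out_dir)
        (out / "quant").mkdir(parents=True, exist_ok=True)
        plate_io.write_layouts(self.layouts, out / "layouts.json")
        for table in self.quant_tables:
            name = f"{table.plate_id}_t{table.time_h:05.1f}.tsv"
            plate_io.write_quant_table(table, out / "quant" / name)
        plate_io.write_halo_scores(self.halos, out / "halos.csv")
        self.truth_isolates.to_csv(out / "truth_isolates.csv", index=False)
        self.truth_pairs.to_csv(out / "truth_pairs.csv", index=False)
        payload = {"config": self.config.to_dict(), "expected_msd": self.expected_msd}
        (out / "config.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
        return out


def _make_precultures(
    config: SimulationConfig, isolate_ids: list[str]
) -> dict[str, list[PlateLayout]]:
    per_plate = config.n_isolates // 4
    plates: dict[str, list[PlateLayout]] = {}
    positions = list(plate_io.iter_positions(96))[:per_plate]
    for medium in config.media:
        plates[medium] = []
        for p in range(4):
            chunk = isolate_ids[p * per_plate : (p + 1) * per_plate]
            occupants = {pos: (iso,) for pos, iso in zip(positions, chunk)}
            plates[medium].append(
                PlateLayout(
                    plate_id=f"{medium}-PRE{p + 1}",
                    array_format=96,
                    medium=medium,
                    role="preculture",
                    occupants=occupants,
                )
            )
    return plates


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a full synthetic experiment from a validated config.

    Deterministic given ``config.seed``.  See the module docstring for the
    generative model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.timepoints, dtype=float)

    isolate_ids = [f"iso{i + 1:04d}" for i in range(config.n_isolates)]
    params = pd.DataFrame(
        {
            "isolate_id": isolate_ids,
            "A": rng.uniform(*config.A_range, size=config.n_isolates),
            "k": rng.uniform(*config.k_range, size=config.n_isolates),
            "t_i": rng.uniform(*config.ti_range, size=config.n_isolates),
        }
    ).set_index("isolate_id")
    params["IF_true"] = [
        gompertz_auc(r.A, r.k, r.t_i, t_max=config.t_max)
        for r in params.itertuples(index=False)
    ]

    # per (medium, target) antifungal truth
    af_truth: dict[tuple[str, str, str], bool] = {}
    truth_iso_rows = []
    for iso in isolate_ids:
        row = {"isolate_id": iso, **params.loc[iso, ["A", "k", "t_i"]].to_dict()}
        for medium in config.media:
            for tgt in config.targets:
                flag = bool(rng.random() < config.antifungal_prevalence)
                af_truth[(iso, medium, tgt)] = flag
                row[f"antifungal_{medium}_{tgt}"] = flag
        truth_iso_rows.append(row)
    truth_isolates = pd.DataFrame(truth_iso_rows)

    precultures = _make_precultures(config, isolate_ids)
    all_layouts: list[PlateLayout] = []
    assembled: dict[str, list[PlateLayout]] = {}
    for medium in config.media:
        assembled[medium] = plate_io.assemble_layouts(precultures[medium])[medium]
        all_layouts.extend(precultures[medium])
        all_layouts.extend(assembled[medium])

    exp_msd = expected_msd(config)
    delta = config.effect_delta_msd * exp_msd

    quant_tables: list[QuantTable] = []
    halo_rows: list[dict] = []
    truth_pair_rows: list[dict] = []

    for medium in config.media:
        plates = assembled[medium]
        msp = plates[0]
        rsps = plates[1:5]
        ints = plates[5:9]
        offsets = {
            p.plate_id: 1.0 + rng.normal(0.0, config.plate_offset_sigma)
            if config.plate_offset_sigma > 0
            else 1.0
            for p in plates
        }

        # curve per (plate, position): (A, k, t_i) before the plate offset
        curves: dict[str, dict[tuple[int, int], tuple[float, float, float]]] = {}
        for plate in (msp, *rsps):
            curves[plate.plate_id] = {
                pos: tuple(params.loc[occ[0], ["A", "k", "t_i"]])
                for pos, occ in plate.occupants.items()
            }
            for pos, occ in sorted(plate.occupants.items()):
                for tgt in config.targets:
                    halo_rows.append(
                        {
                            "plate_id": plate.plate_id,
                            "position": position_label(*pos),
                            "target": tgt,
                            "antifungal": af_truth[(occ[0], medium, tgt)],
                        }
                    )

        for i, inter in enumerate(ints):
            curves[inter.plate_id] = {}
            for pos, (iso1, iso2) in sorted(inter.occupants.items()):
                p1 = params.loc[iso1]
                p2 = params.loc[iso2]
                if1, if2 = float(p1["IF_true"]), float(p2["IF_true"])
                dom = p1 if if1 >= if2 else p2
                if_dom = max(if1, if2)
                if iso1 == iso2:
                    eco_true = "self"
                    if_target = if_dom
                else:
                    u = rng.random()
                    if u < config.frac_cooperative:
                        eco_true = "cooperation"
                        if_target = if_dom + delta
                    elif u < config.frac_cooperative + config.frac_competitive:
                        eco_true = "competition"
                        if_target = min(if1, if2) - delta
                        if if_target <= 0:
                            if_target = 0.5 * min(if1, if2)
                    else:
                        eco_true = "neutral"
                        jitter = (
                            rng.uniform(-1.0, 1.0)
                            * config.neutral_jitter_msd
                            * exp_msd
                        )
                        if_target = if_dom + jitter
                scale = if_target / if_dom
                curves[inter.plate_id][pos] = (
                    float(dom["A"]) * scale,
                    float(dom["k"]),
                    float(dom["t_i"]),
                )

                # halo phenotype of the pair, with suppression/induction
                pair_truth = {}
                for tgt in config.targets:
                    h1 = af_truth[(iso1, medium, tgt)]
                    h2 = af_truth[(iso2, medium, tgt)]
                    base = h1 or h2
                    if iso1 == iso2:
                        hp = h1
                    elif base:
                        hp = not (rng.random() < config.p_suppression)
                    else:
                        hp = rng.random() < config.p_induction
                    pair_truth[tgt] = (hp, h1, h2)
                    halo_rows.append(
                        {
                            "plate_id": inter.plate_id,
                            "position": position_label(*pos),
                            "target": tgt,
                            "antifungal": hp,
                        }
                    )
                rec = {
                    "pair_id": f"{inter.plate_id}:{position_label(*pos)}",
                    "medium": medium,
                    "plate_id": inter.plate_id,
                    "position": position_label(*pos),
                    "isolate_1": iso1,
                    "isolate_2": iso2,
                    "is_self": iso1 == iso2,
                    "eco_class_true": eco_true,
                    "IF_pair_true": if_target,
                    "IF_ind1_true": if1,
                    "IF_ind2_true": if2,
                }
                for tgt in config.targets:
                    hp, h1, h2 = pair_truth[tgt]
                    rec[f"halo_pair_{tgt}"] = hp
                    rec[f"func_class_true_{tgt}"] = (
                        "self" if iso1 == iso2 else classify_functional(hp, h1, h2)
                    )
                truth_pair_rows.append(rec)

        # observations: Gompertz curve (+ plate offset on A) + noise, dropout
        for plate in plates:
            plate_curves = curves[plate.plate_id]
            positions = sorted(plate_curves)
            n = len(positions)
            factor = offsets[plate.plate_id]
            y_true = np.empty((n, len(t)))
            for j, pos in enumerate(positions):
                a, k, ti = plate_curves[pos]
                y_true[j] = gompertz(t, a * factor, k, ti)
            noise = (
                rng.normal(0.0, config.noise_sigma, size=y_true.shape)
                if config.noise_sigma > 0
                else 0.0
            )
            y_obs = y_true + noise
            keep = (
                rng.random(size=y_true.shape) >= config.dropout_p
                if config.dropout_p > 0
                else np.ones(y_true.shape, dtype=bool)
            )
            half = np.power(2.0, y_obs / 2.0)
            for ti_idx, time_h in enumerate(t):
                rows = [
                    (pos[0], pos[1], half[j, ti_idx], half[j, ti_idx])
                    for j, pos in enumerate(positions)
                    if keep[j, ti_idx]
                ]
                quant_tables.append(
                    QuantTable(
                        plate_id=plate.plate_id,
                        time_h=float(time_h),
                        array_format=384,
                        data=pd.DataFrame(
                            rows, columns=["row", "col", "size", "opacity"]
                        ),
                    )
                )

    halos = pd.DataFrame(halo_rows)
    rc = halos["position"].map(plate_io.parse_position)
    halos["row"] = [p[0] for p in rc]
    halos["col"] = [p[1] for p in rc]
    return SimulatedExperiment(
        config=config,
        layouts=all_layouts,
        quant_tables=quant_tables,
        halos=halos,
        truth_isolates=truth_isolates,
        truth_pairs=pd.DataFrame(truth_pair_rows),
        expected_msd=exp_msd,
    )
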