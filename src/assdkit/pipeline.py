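"""End-to-end orchestration: miscibility table, formulation arithmetic,
toy-trajectory studies and machine/human-readable reports.

Everything is a pure function of (configuration, seeds): reports contain no
wall-clock information, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__ as _version
from . import gcontrib
from .formulation import (
    CELECOXIB_MASS_DA,
    DoseScenario,
    celecoxib_unit,
    counterion_mass_ratio,
    drug_oligomer_mass_ratio,
    hpmcas_15mer,
    ions_for_molarity,
    oligomer_mass,
    pvpva_34mer,
    supersaturation_ratio,
)
from .toysim import ToySimParams, build_toy_system, run_toy_dynamics
from .trajkit import (
    HBondCriterion,
    aggregates_series,
    compute_rdf,
    drug_drug_energy,
    drug_oligomer_energy,
    equilibration_split,
    hbond_occupancy,
    rmsd_series,
    toy_energy_backend,
)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "StageError",
    "run_miscibility",
    "formulation_table",
    "run_trajectory_study",
    "demo_end_to_end",
    "aggregation_propensity_study",
    "oligomer_competition_study",
]


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage for diagnosis."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


class ToysimConfig(BaseModel):
    n_drug: int = 13
    charge_state: Literal["neutral", "anionic"] = "neutral"
    with_oligomer: bool = True
    box_edge: float = 34.0
    n_steps: int = 4000
    dt: float = 0.02
    friction: float = 0.25
    temperature: float = 0.4
    drug_eps_scale: float = 1.0
    oligomer_eps_scale: float = 1.0
    snapshot_interval: int = 40


class AnalysisConfig(BaseModel):
    contact_cutoff: float = 4.0
    stride_ps: float = 100.0
    hbond_d_max: float = 3.2
    hbond_angle_min: float = 158.0
    rdf_dr: float = 0.1
    n_boot: int = 500


class StudyConfig(BaseModel):
    """One study = miscibility screen + a toy trajectory + its analysis."""

    temperature: float = 298.15
    toysim: ToysimConfig = Field(default_factory=ToysimConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seed: int = 2023


class MiscibilityRow(BaseModel):
    compound: str
    delta_fedors: float
    delta_hvk: float
    delta_mean: float
    delta_mismatch: float | None = None
    chi: float | None = None
    verdict: str | None = None


class TrajectorySummary(BaseModel):
    n_frames: int
    equilibration_start: int
    rdf_peak_r: float | None = None
    rdf_peak_g: float | None = None
    hbond_class_occupancy: float | None = None
    mean_largest_aggregate: float
    final_largest_aggregate: int
    e_drug_drug_mean: float | None = None
    e_drug_drug_sd: float | None = None
    e_drug_drug_ci: tuple[float, float] | None = None
    e_drug_oligomer_mean: float | None = None
    e_drug_oligomer_sd: float | None = None
    e_drug_oligomer_ci: tuple[float, float] | None = None
    n_energy_samples: int = 0


class StudyReport(BaseModel):
    """Machine-readable study output (seeds recorded for provenance)."""

    version: str
    seed: int
    config: StudyConfig
    miscibility: list[MiscibilityRow]
    formulation: dict[str, float]
    trajectory: TrajectorySummary | None = None


def run_miscibility(
    temperature: float = 298.15,
    table: gcontrib.GroupContributionTable | None = None,
) -> pd.DataFrame:
    """Solubility-parameter screening table for the reference drug/polymers.

    One row per compound with the Fedors and HVK parameters, their mean, the
    drug-polymer mismatch, the Flory-Huggins chi (lattice volume = drug
    Fedors molar volume) and the miscibility verdict.
    """
    table = table if table is not None else gcontrib.load_default_table()
    decomps = gcontrib.load_reference_decompositions()
    cel = decomps["celecoxib"]
    drug_pair = (gcontrib.fedors_delta(cel, table), gcontrib.hvk_delta(cel, table))

    vp, va = decomps["vinylpyrrolidone"], decomps["vinyl_acetate"]
    pvpva_pair = tuple(
        gcontrib.polymer_delta([(vp, 0.6), (va, 0.4)], table, method=m)
        for m in ("fedors", "hvk")
    )
    hpm = decomps["hpmcas_average_monomer"]
    hpmcas_pair = (gcontrib.fedors_delta(hpm, table), gcontrib.hvk_delta(hpm, table))

    rows = [
        {
            "compound": "CEL",
            "delta_fedors": drug_pair[0].delta,
            "delta_hvk": drug_pair[1].delta,
            "delta_mean": (drug_pair[0].delta + drug_pair[1].delta) / 2,
            "delta_mismatch": math.nan,
            "chi": math.nan,
            "verdict": "",
        }
    ]
    for name, pair in (("PVP-VA", pvpva_pair), ("HPMCAS", hpmcas_pair)):
        report = gcontrib.miscibility_report(drug_pair, pair, T=temperature)
        rows.append(
            {
                "compound": name,
                "delta_fedors": pair[0].delta,
                "delta_hvk": pair[1].delta,
                "delta_mean": report.delta_polymer,
                "delta_mismatch": report.delta_mismatch,
                "chi": report.chi,
                "verdict": report.verdict,
            }
        )
    return pd.DataFrame(rows)


def formulation_table() -> dict[str, float]:
    """The reference formulation arithmetic in one dictionary."""
    m_cel = CELECOXIB_MASS_DA
    pvpva = oligomer_mass(pvpva_34mer())
    hpmcas = oligomer_mass(hpmcas_15mer())
    return {
        "celecoxib_mass_da": round(celecoxib_unit().mass, 1),
        "pvpva_34mer_mass_da": round(pvpva, 1),
        "hpmcas_15mer_mass_da": round(hpmcas, 1),
        "cel_pvpva_mass_ratio": drug_oligomer_mass_ratio(13, m_cel, pvpva).rounded,
        "cel_hpmcas_mass_ratio": drug_oligomer_mass_ratio(11, m_cel, hpmcas).rounded,
        "na_cel_mass_ratio": round(counterion_mass_ratio(22.99, m_cel), 4),
        "naoh_cel_mass_ratio": round(counterion_mass_ratio(40.00, m_cel), 3),
        "supersaturation_fold": float(
            f"{supersaturation_ratio(DoseScenario(200.0, 35.0, 3.46)):.3g}"
        ),
        "ion_pairs_106A_0.01M": ions_for_molarity((106.0,) * 3, 0.01),
        "ion_pairs_112A_0.01M": ions_for_molarity((112.0,) * 3, 0.01),
    }


def _trajectory_stage(config: StudyConfig) -> tuple[TrajectorySummary, dict]:
    ts = config.toysim
    an = config.analysis
    system = build_toy_system(
        n_drug=ts.n_drug,
        charge_state=ts.charge_state,
        with_oligomer=ts.with_oligomer,
        box_edge=ts.box_edge,
        seed=config.seed,
        drug_eps_scale=ts.drug_eps_scale,
        oligomer_eps_scale=ts.oligomer_eps_scale,
    )
    params = ToySimParams(
        n_steps=ts.n_steps,
        dt=ts.dt,
        friction=ts.friction,
        temperature=ts.temperature,
        drug_eps_scale=ts.drug_eps_scale,
        oligomer_eps_scale=ts.oligomer_eps_scale,
        seed=config.seed,
        snapshot_interval=ts.snapshot_interval,
    )
    traj = run_toy_dynamics(system, params)
    if traj.n_frames < 4:
        raise ValueError(
            f"insufficient frames ({traj.n_frames}) for an equilibration split"
        )
    top = traj.topology

    rmsd = rmsd_series(traj)
    start = equilibration_split(rmsd)
    frames = list(range(start, traj.n_frames))

    donors = top.select(species="drug", role="donor")
    if ts.with_oligomer:
        acceptors = top.select(species="oligomer", role="acceptor")
    else:
        acceptors = top.select(species="drug", role="acceptor")
    rdf = compute_rdf(
        traj, donors, acceptors, dr=an.rdf_dr, frames=frames
    )
    hb = hbond_occupancy(
        traj,
        donors,
        acceptors,
        HBondCriterion(an.hbond_d_max, an.hbond_angle_min),
        frames=frames,
    )
    aggs = aggregates_series(
        traj, contact_cutoff=an.contact_cutoff, frames=frames
    )
    largest = aggs.largest_sizes()

    backend = toy_energy_backend(top, dielectric=4.0, solvation=True)
    e_dd = drug_drug_energy(
        traj,
        backend,
        contact_cutoff=an.contact_cutoff,
        stride_ps=an.stride_ps,
        start_frame=start,
        n_boot=an.n_boot,
        seed=config.seed,
    )
    peak_r, peak_g = rdf.first_peak()
    summary = TrajectorySummary(
        n_frames=traj.n_frames,
        equilibration_start=start,
        rdf_peak_r=peak_r,
        rdf_peak_g=peak_g,
        hbond_class_occupancy=hb.class_occupancy,
        mean_largest_aggregate=float(largest.mean()),
        final_largest_aggregate=int(largest[-1]),
        n_energy_samples=e_dd.n_samples,
    )
    if not e_dd.empty:
        boot = e_dd.bootstrap.get("E_total")
        summary.e_drug_drug_mean = e_dd.mean("E_total")
        summary.e_drug_drug_sd = e_dd.sd("E_total")
        if boot:
            summary.e_drug_drug_ci = (boot.ci_low, boot.ci_high)
    artifacts = {"rdf": rdf, "hbonds": hb, "aggregates": aggs, "energy_dd": e_dd}
    if ts.with_oligomer:
        e_do = drug_oligomer_energy(
            traj,
            backend,
            contact_cutoff=an.contact_cutoff,
            stride_ps=an.stride_ps,
            start_frame=start,
            n_boot=an.n_boot,
            seed=config.seed,
        )
        artifacts["energy_do"] = e_do
        if not e_do.empty:
            boot = e_do.bootstrap.get("E_drug_oligomer")
            summary.e_drug_oligomer_mean = e_do.mean("E_drug_oligomer")
            summary.e_drug_oligomer_sd = e_do.sd("E_drug_oligomer")
            if boot:
                summary.e_drug_oligomer_ci = (boot.ci_low, boot.ci_high)
    return summary, artifacts


def _write_report(report: StudyReport, artifacts: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as handle:
        handle.write(report.model_dump_json(indent=2))
        handle.write("\n")
    misc = pd.DataFrame([row.model_dump() for row in report.miscibility])
    misc["verdict"] = misc["verdict"].fillna("")
    misc.to_csv(outdir / "miscibility.csv", index=False, float_format="%.6g")
    if "rdf" in artifacts:
        rdf = artifacts["rdf"]
        pd.DataFrame(
            {"r": rdf.bin_centers, "g": rdf.g, "counts": rdf.counts}
        ).to_csv(outdir / "rdf.csv", index=False, float_format="%.6g")
    if "hbonds" in artifacts:
        hb = artifacts["hbonds"]
        rows = [
            {"donor": d, "acceptor": a, "occupancy": occ}
            for (d, a), occ in sorted(hb.pair_occupancy.items())
        ]
        pd.DataFrame(rows).to_csv(
            outdir / "hbonds.csv", index=False, float_format="%.6g"
        )
    if "energy_dd" in artifacts and not artifacts["energy_dd"].empty:
        artifacts["energy_dd"].records.to_csv(
            outdir / "energies_drug_drug.csv", index=False, float_format="%.8g"
        )
    if "energy_do" in artifacts and not artifacts["energy_do"].empty:
        artifacts["energy_do"].records.to_csv(
            outdir / "energies_drug_oligomer.csv", index=False, float_format="%.8g"
        )
    lines = [
        f"assdkit study report (version {report.version}, seed {report.seed})",
        "",
        "Miscibility (MPa^1/2):",
        misc.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        "",
        "Formulation arithmetic:",
    ]
    lines += [f"  {k} = {v}" for k, v in report.formulation.items()]
    if report.trajectory is not None:
        t = report.trajectory
        lines += [
            "",
            "Trajectory analysis:",
            f"  frames {t.n_frames}, equilibration from frame {t.equilibration_start}",
            f"  RDF first peak g(r) = {t.rdf_peak_g:.2f} at r = {t.rdf_peak_r:.2f} A",
            f"  donor->acceptor H-bond class occupancy = {t.hbond_class_occupancy:.3f}",
            f"  mean/final largest aggregate = "
            f"{t.mean_largest_aggregate:.2f} / {t.final_largest_aggregate}",
        ]
        if t.e_drug_drug_mean is not None:
            lines.append(
                f"  E(drug:drug) = {t.e_drug_drug_mean:.2f} "
                f"+/- {t.e_drug_drug_sd:.2f} kcal/mol "
                f"({t.n_energy_samples} samples)"
            )
        if t.e_drug_oligomer_mean is not None:
            lines.append(
                f"  E(drug:oligomer) = {t.e_drug_oligomer_mean:.2f} "
                f"+/- {t.e_drug_oligomer_sd:.2f} kcal/mol"
            )
    with open(outdir / "summary.txt", "w") as handle:
        handle.write("\n".join(lines) + "\n")


def run_trajectory_study(
    config: StudyConfig, outdir: str | Path | None = None
) -> StudyReport:
    """Full study: miscibility screen, formulation arithmetic, toy
    trajectory, structural and energetic analysis, written reports.

    Any stage failure aborts with a stage-named :class:`StageError`; partial
    outputs are removed.
    """
    stage = "miscibility"
    try:
        misc = run_miscibility(temperature=config.temperature)
        stage = "formulation"
        form = formulation_table()
        stage = "trajectory"
        summary, artifacts = _trajectory_stage(config)
        report = StudyReport(
            version=_version,
            seed=config.seed,
            config=config,
            miscibility=[
                MiscibilityRow(
                    compound=r.compound,
                    delta_fedors=r.delta_fedors,
                    delta_hvk=r.delta_hvk,
                    delta_mean=r.delta_mean,
                    delta_mismatch=None if math.isnan(r.delta_mismatch) else r.delta_mismatch,
                    chi=None if math.isnan(r.chi) else r.chi,
                    verdict=r.verdict or None,
                )
                for r in misc.itertuples()
            ],
            formulation=form,
            trajectory=summary,
        )
        if outdir is not None:
            stage = "report"
            _write_report(report, artifacts, Path(outdir))
        return report
    except StageError:
        raise
    except Exception as exc:
        if outdir is not None:
            for name in (
                "report.json", "miscibility.csv", "rdf.csv", "hbonds.csv",
                "energies_drug_drug.csv", "energies_drug_oligomer.csv",
                "summary.txt",
            ):
                path = Path(outdir) / name
                if path.exists():
                    path.unlink()
        raise StageError(stage, exc) from exc


def demo_end_to_end(seed: int = 2023, outdir: str | Path | None = None) -> StudyReport:
    """Small deterministic end-to-end run: reference miscibility table,
    formulation arithmetic, one neutral drug+oligomer toy trajectory and its
    full analysis.  Designed to complete in well under a minute."""
    config = StudyConfig(
        seed=seed,
        toysim=ToysimConfig(
            n_drug=8,
            charge_state="neutral",
            with_oligomer=True,
            box_edge=30.0,
            n_steps=4000,
            drug_eps_scale=2.5,
            snapshot_interval=40,
        ),
        analysis=AnalysisConfig(stride_ps=10.0, n_boot=200, contact_cutoff=5.5),
    )
    return run_trajectory_study(config, outdir)


def report_schema() -> dict:
    """JSON schema of :class:`StudyReport` (also shipped as a data file)."""
    return StudyReport.model_json_schema()


def load_shipped_schema() -> dict:
    path = Path(resources.files("assdkit").joinpath("data", "report_schema.json"))  # type: ignore[arg-type]
    with open(path) as handle:
        return json.load(handle)


#: Toy-study conditions: a supersaturated 13-molecule box scaled down to
#: bead resolution.  The neutral arm runs at strong drug-drug attraction
#: (3.5 kcal/mol core wells), the anionic arm at weak attraction with -1
#: drug charges and counterions; the 5.5 A contact cutoff matches the
#: Lennard-Jones contact distance (~4.5 A) of the 4 A beads.
TOY_STUDY = dict(
    box_edge=34.0,
    n_steps=20_000,
    friction=0.25,
    temperature=0.4,
    snapshot_interval=100,
    contact_cutoff=5.5,
)


def aggregation_propensity_study(
    seeds: list[int],
    n_drug: int = 13,
    neutral_eps: float = 3.5,
    anionic_eps: float = 0.2,
) -> pd.DataFrame:
    """Matched neutral vs anionic runs: final largest aggregate per seed.

    Neutral drugs at full Lennard-Jones attraction coalesce into one large
    aggregate; anionic drugs (net -1 each, with counterions, at reduced
    attraction) stay dispersed -- the qualitative contrast seen between the
    reference neutral and anionic drug simulations.
    """
    rows = []
    for seed in seeds:
        sizes = {}
        for state, eps in (("neutral", neutral_eps), ("anionic", anionic_eps)):
            system = build_toy_system(
                n_drug,
                state,
                with_oligomer=False,
                box_edge=TOY_STUDY["box_edge"],
                seed=seed,
                drug_eps_scale=eps,
            )
            params = ToySimParams(
                n_steps=TOY_STUDY["n_steps"],
                friction=TOY_STUDY["friction"],
                temperature=TOY_STUDY["temperature"],
                snapshot_interval=TOY_STUDY["snapshot_interval"],
                seed=seed,
                drug_eps_scale=eps,
            )
            traj = run_toy_dynamics(system, params)
            clusters = aggregates_series(
                traj,
                contact_cutoff=TOY_STUDY["contact_cutoff"],
                frames=[traj.n_frames - 1],
            )
            sizes[state] = int(clusters.largest_sizes()[0])
        rows.append(
            {
                "seed": seed,
                "neutral_largest": sizes["neutral"],
                "anionic_largest": sizes["anionic"],
            }
        )
    return pd.DataFrame(rows)


def oligomer_competition_study(
    seeds: list[int],
    eps_low: float = 0.3,
    eps_high: float = 10.0,
    n_drug: int = 10,
    drug_eps_scale: float = 1.5,
    stride_ps: float = 10.0,
) -> pd.DataFrame:
    """Matched toy runs differing only in drug-oligomer attraction.

    For each seed, two drug+oligomer systems are simulated with a weakly and
    a strongly attractive oligomer; reported is the mean |drug:drug|
    interaction energy of each.  A stronger oligomer competes drug molecules
    away from each other, weakening drug:drug interactions.
    """
    rows = []
    for seed in seeds:
        means = {}
        for label, eps in (("low", eps_low), ("high", eps_high)):
            system = build_toy_system(
                n_drug,
                "neutral",
                with_oligomer=True,
                box_edge=TOY_STUDY["box_edge"],
                seed=seed,
                drug_eps_scale=drug_eps_scale,
                oligomer_eps_scale=eps,
            )
            params = ToySimParams(
                n_steps=TOY_STUDY["n_steps"],
                friction=TOY_STUDY["friction"],
                temperature=TOY_STUDY["temperature"],
                snapshot_interval=TOY_STUDY["snapshot_interval"],
                seed=seed,
                drug_eps_scale=drug_eps_scale,
                oligomer_eps_scale=eps,
            )
            traj = run_toy_dynamics(system, params)
            backend = toy_energy_backend(traj.topology, dielectric=20.0)
            report = drug_drug_energy(
                traj,
                backend,
                contact_cutoff=TOY_STUDY["contact_cutoff"],
                stride_ps=stride_ps,
                seed=seed,
            )
            means[label] = (
                abs(report.mean("E_total")) if not report.empty else 0.0
            )
        rows.append(
            {
                "seed": seed,
                "mean_abs_Edd_weak_oligomer": means["low"],
                "mean_abs_Edd_strong_oligomer": means["high"],
            }
        )
    return pd.DataFrame(rows)
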