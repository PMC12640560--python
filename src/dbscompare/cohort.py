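"""Synthetic cohort generator.

Produces complete subject datasets with the statistical structure the
evaluation assumes: an STN-like gray ellipsoid straddling the distal
contacts, an internal-capsule-like slab farther from the lead, a thin-fiber
bundle (HDP analog, 4 um) hugging the lead and terminating in the STN
ellipsoid, a far large-fiber bundle (CSBT analog, 12 um) running inside the
capsule slab, a per-subject smooth random deformation field standing in for
normative-space registration, and zero-inflated evoked-potential amplitudes
tied to a designated ground-truth activation model.

The cohort mirrors the experimental bookkeeping table: lead models, the
8/3 standard/steerable split and per-subject monopolar/bipolar setting
counts are taken from its rows.  Ground truth is an explicit model variant
(default: driving force, native space, pathway representation); the
documentation states this circularity plainly — ranking recovery is then a
well-posed test of the comparison machinery, not an independent
physiological simulation.

Everything is deterministic under the cohort seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import leads as leads_mod
from .anatomy import DeformationField, Pathway, Structure, SubjectDataset
from .leads import LeadPlacement, StimSetting, build_lead, lead_to_world, load_experiment_table, world_to_lead

__all__ = ["EPModel", "CohortSpec", "generate_anatomy", "generate_deformation",
           "generate_settings", "generate_ep_table", "generate_subject", "generate_cohort"]


@dataclass(frozen=True)
class EPModel:
    """Evoked-potential amplitude model.

    EP1 (short latency) indexes HDP activation, EP0 (very short latency)
    indexes CSBT activation.  Amplitudes are on an arbitrary uV-like scale:
    only correlation/presence statistics ever consume them.  The detection
    floor acts on the true response amplitude — a response below the
    recording floor is never detected — so a subject whose CSBT truth is
    zero everywhere reads EP0 = 0 for every setting.  Near-floor responses
    are additionally zero-inflated with probability
    ``ep0_zero_inflation * exp(-truth% / near_threshold_scale)``.
    """

    gain: float = 1.0  # uV per % activation
    noise_sd: float = 5.0  # uV (5% of the 100 uV full scale)
    ep0_zero_inflation: float = 0.85
    detection_floor: float = 2.0  # uV
    near_threshold_scale: float = 15.0  # % activation
    truth_variant: str = "DF-Native-Pathway"

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.noise_sd < 0:
            raise ValueError("gain must be positive and noise_sd non-negative")
        if not 0.0 <= self.ep0_zero_inflation <= 1.0:
            raise ValueError("ep0_zero_inflation must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 11
    seed: int = 0
    # anatomy (lead-frame mm unless noted)
    stn_semiaxes: tuple[float, float, float] = (3.0, 2.5, 4.5)
    stn_center: tuple[float, float, float] = (1.5, 0.5, 3.5)
    ic_offset: float = 4.5  # slab center distance from the lead axis
    ic_thickness: float = 3.0
    hdp_offset: float = 1.6  # mean closest approach of HDP fibers
    hdp_spread: float = 0.7
    csbt_offset: float = 4.5  # mean closest approach of CSBT fibers
    csbt_spread: float = 0.6
    fibers_per_bundle: int = 100
    hdp_diameter_um: float = 4.0
    csbt_diameter_um: float = 12.0
    anatomy_spacing: float = 0.5  # mm, structure-mask lattice
    # settings
    amplitudes_mA: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    pulse_width_us: float = 60.0
    frequency_hz: float = 10.0
    # normative-space emulation
    warp_magnitude: float = 1.0  # mean |displacement| mm
    warp_smoothness: float = 6.0  # mm, gaussian correlation length
    global_scale: float = 1.0  # >1 emulates the large template brain
    ep_model: EPModel = field(default_factory=EPModel)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("cohort needs at least 2 subjects")
        for v in (*self.stn_semiaxes, self.ic_offset, self.ic_thickness, self.hdp_offset,
                  self.csbt_offset, self.anatomy_spacing):
            if v <= 0:
                raise ValueError("geometric parameters must be positive")
        if self.csbt_offset <= self.hdp_offset:
            raise ValueError("CSBT bundle must be farther from the lead than HDP")


def _table_rows(spec: CohortSpec) -> pd.DataFrame:
    t1 = load_experiment_table()
    rows = [t1.iloc[i % len(t1)] for i in range(spec.n_subjects)]
    return pd.DataFrame(rows).reset_index(drop=True)


def generate_placement(row: pd.Series, rng: np.random.Generator) -> LeadPlacement:
    tip = np.array([row["tip_x_mm"], row["tip_y_mm"], row["tip_z_mm"]], float)
    lateral = np.sign(tip[0]) if tip[0] != 0 else 1.0
    axis = np.array([0.25 * lateral, 0.10, 1.0]) + rng.normal(0.0, 0.05, 3)
    axis /= np.linalg.norm(axis)
    roll = float(rng.uniform(0.0, 360.0))
    return LeadPlacement(tuple(tip), tuple(axis), roll)


def _anatomy_grid(placement: LeadPlacement, lead, spacing: float) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Axis-aligned world lattice (affine, shape) covering the periprosthetic
    anatomy."""
    center = lead_to_world(np.array([[0.0, 0.0, lead.top_z / 2.0]]), placement)[0]
    half = 14.0
    n = int(np.ceil(2 * half / spacing)) + 1
    origin = center - spacing * (n - 1) / 2.0
    affine = np.eye(4)
    affine[:3, :3] *= spacing
    affine[:3, 3] = origin
    return affine, (n, n, n)


def _quadratic_bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def generate_anatomy(
    spec: CohortSpec,
    lead,
    placement: LeadPlacement,
    rng: np.random.Generator,
) -> tuple[dict[str, Structure], dict[str, Pathway]]:
    """Structures (STN-like, IC-like, gray map) and pathways (HDP-like,
    CSBT-like) for one subject, in world space."""
    affine, shape = _anatomy_grid(placement, lead, spec.anatomy_spacing)
    ii = np.indices(shape).reshape(3, -1).T.astype(float)
    world = ii @ affine[:3, :3].T + affine[:3, 3]
    pl = world_to_lead(world, placement)

    stn_c = np.asarray(spec.stn_center, float) + rng.normal(0.0, 0.4, 3)
    semi = np.asarray(spec.stn_semiaxes, float) * rng.uniform(0.92, 1.08, 3)
    stn = (np.sum(((pl - stn_c) / semi) ** 2, axis=1) <= 1.0).reshape(shape)
    if not stn.any():
        raise ValueError("anatomy parameters place the STN outside the lattice")

    phi_ic = rng.uniform(0.0, 2 * np.pi)
    u = np.array([np.cos(phi_ic), np.sin(phi_ic), 0.0])
    proj = pl @ u
    lat = pl - np.outer(proj, u)
    ic = (
        (proj >= spec.ic_offset - spec.ic_thickness / 2.0)
        & (proj <= spec.ic_offset + spec.ic_thickness / 2.0)
        & (np.abs(lat[:, 2] - lead.top_z / 2.0) <= 12.0)
        & (np.abs(lat @ np.array([-np.sin(phi_ic), np.cos(phi_ic), 0.0])) <= 8.0)
    ).reshape(shape)

    structures = {
        "STN": Structure("STN", stn, affine.copy()),
        "IC": Structure("IC", ic, affine.copy()),
        "gray": Structure("gray", stn.copy(), affine.copy()),
    }

    n = spec.fibers_per_bundle
    # HDP: thin fibers sweeping past the distal contacts into the STN
    hdp: list[np.ndarray] = []
    for _ in range(n):
        d = max(float(rng.normal(spec.hdp_offset, spec.hdp_spread)), 1.25)
        az = rng.uniform(0.0, 2 * np.pi)
        zw = rng.uniform(1.5, 5.0)
        w = np.array([d * np.cos(az), d * np.sin(az), zw])
        e = stn_c + rng.uniform(-0.6, 0.6, 3) * semi * 0.7
        up = w - e
        nrm = np.linalg.norm(up)
        up = up / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        s = w + up * 18.0 + rng.normal(0.0, 1.0, 3)
        fiber = _quadratic_bezier(s, w, e, 48)
        hdp.append(lead_to_world(fiber, placement))
    # CSBT: thick, coherent far bundle descending inside the capsule slab
    csbt: list[np.ndarray] = []
    for _ in range(n):
        d = max(float(rng.normal(spec.csbt_offset, spec.csbt_spread)), 3.0)
        az = phi_ic + rng.normal(0.0, np.deg2rad(8.0))
        x0 = np.array([d * np.cos(az), d * np.sin(az), 0.0])
        tilt = rng.normal(0.0, 0.03, 2)
        z = np.linspace(-10.0, 30.0, 60)
        wob = 0.3 * np.sin(z / 9.0 + rng.uniform(0, 2 * np.pi))
        pts = np.column_stack(
            [x0[0] + tilt[0] * z + wob, x0[1] + tilt[1] * z + wob * 0.5, z]
        )
        csbt.append(lead_to_world(pts, placement))

    pathways = {
        "HDP": Pathway("HDP", hdp, spec.hdp_diameter_um),
        "CSBT": Pathway("CSBT", csbt, spec.csbt_diameter_um),
    }
    return structures, pathways


def generate_deformation(
    spec: CohortSpec,
    lead,
    placement: LeadPlacement,
    rng: np.random.Generator,
) -> DeformationField:
    """Smooth random displacement field emulating nonlinear normalization to
    a template, optionally composed with a global scaling about the anatomy
    center (templates are larger than the average brain)."""
    spacing = 2.0
    center = lead_to_world(np.array([[0.0, 0.0, lead.top_z / 2.0]]), placement)[0]
    half = 25.0
    nvox = int(np.ceil(2 * half / spacing)) + 1
    origin = center - spacing * (nvox - 1) / 2.0
    affine = np.eye(4)
    affine[:3, :3] *= spacing
    affine[:3, 3] = origin

    noise = rng.normal(0.0, 1.0, (nvox, nvox, nvox, 3))
    sig = spec.warp_smoothness / spacing
    for k in range(3):
        noise[..., k] = gaussian_filter(noise[..., k], sig, mode="nearest")
    mag = np.linalg.norm(noise, axis=-1).mean()
    if mag > 0 and spec.warp_magnitude > 0:
        noise *= spec.warp_magnitude / mag
    else:
        noise[:] = 0.0
    if spec.global_scale != 1.0:
        ii = np.indices((nvox, nvox, nvox)).reshape(3, -1).T.astype(float)
        world = (ii @ affine[:3, :3].T + affine[:3, 3]).reshape(nvox, nvox, nvox, 3)
        noise += (spec.global_scale - 1.0) * (world - center)
    return DeformationField(noise, affine)


def generate_settings(spec: CohortSpec, lead, n_monopolar: int, n_bipolar: int) -> list[StimSetting]:
    """Settings menu mirroring one bookkeeping-table row: the requested
    numbers of monopolar and bipolar settings drawn in order from the full
    configuration x amplitude product."""
    mono_configs: list[list[int]] = [[c.index] for c in lead.contacts]
    for level in range(lead.n_levels):
        cs = lead.contacts_at_level(level)
        if len(cs) > 1:  # pseudo ring: all segments of one level together
            mono_configs.append([c.index for c in cs])
    pairs = [(i, i + 1) for i in range(lead.n_contacts - 1)]
    pairs += [(0, lead.n_contacts - 1)]
    bi_configs = [{"cathodes": [a], "anodes": [b]} for a, b in pairs]
    bi_configs += [{"cathodes": [b], "anodes": [a]} for a, b in pairs]

    menu = {
        "monopolar": mono_configs,
        "amplitudes_mA": list(spec.amplitudes_mA),
        "pulse_width_us": spec.pulse_width_us,
        "frequency_hz": spec.frequency_hz,
    }
    mono = leads_mod.enumerate_settings(lead, menu) if n_monopolar else []
    menu_b = dict(menu)
    menu_b.pop("monopolar")
    menu_b["bipolar"] = bi_configs
    bi = leads_mod.enumerate_settings(lead, menu_b) if n_bipolar else []
    if n_monopolar > len(mono) or n_bipolar > len(bi):
        raise ValueError("requested more settings than the menu provides")
    return mono[:n_monopolar] + bi[:n_bipolar]


def generate_ep_table(
    truth: pd.DataFrame,
    ep: EPModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Evoked-potential amplitudes from ground-truth activation.

    ``truth`` has columns setting_id, hdp_pct, csbt_pct.
    """
    n = len(truth)
    ep1 = np.maximum(ep.gain * truth["hdp_pct"].to_numpy() + rng.normal(0.0, ep.noise_sd, n), 0.0)
    sig0 = ep.gain * truth["csbt_pct"].to_numpy()
    ep0 = np.maximum(sig0 + rng.normal(0.0, ep.noise_sd, n), 0.0)
    ep0[sig0 < ep.detection_floor] = 0.0
    p_drop = ep.ep0_zero_inflation * np.exp(-truth["csbt_pct"].to_numpy() / ep.near_threshold_scale)
    ep0[rng.random(n) < p_drop] = 0.0
    return pd.DataFrame(
        {"setting_id": truth["setting_id"], "EP0_uV": ep0, "EP1_uV": ep1}
    )


def generate_subject(
    spec: CohortSpec,
    index: int,
    row: pd.Series,
    seed_seq: np.random.SeedSequence,
    eval_options=None,
) -> SubjectDataset:
    from .evaluate import EvalOptions, VariantSpec, run_variant

    rng = np.random.default_rng(seed_seq)
    lead = build_lead(row["lead_name"])
    placement = generate_placement(row, rng)
    structures, pathways = generate_anatomy(spec, lead, placement, rng)
    deformation = generate_deformation(spec, lead, placement, rng)
    settings = generate_settings(spec, lead, int(row["n_monopolar"]), int(row["n_bipolar"]))

    subject = SubjectDataset(
        subject_id=f"S{index + 1:02d}",
        space="native",
        lead_name=lead.name,
        placement=placement,
        structures=structures,
        pathways=pathways,
        settings=settings,
        ep_table=pd.DataFrame(
            {"setting_id": [s.setting_id for s in settings], "EP0_uV": 0.0, "EP1_uV": 0.0}
        ),
        deformation=deformation,
    )
    opts = eval_options if eval_options is not None else EvalOptions()
    truth_act = run_variant(subject, VariantSpec.parse(spec.ep_model.truth_variant), opts)
    wide = truth_act.pivot_table(index="setting_id", columns="pathway", values="value", sort=False)
    truth = pd.DataFrame(
        {
            "setting_id": [s.setting_id for s in settings],
            "hdp_pct": wide["HDP"].reindex([s.setting_id for s in settings]).to_numpy(),
            "csbt_pct": wide["CSBT"].reindex([s.setting_id for s in settings]).to_numpy(),
        }
    )
    subject.truth = truth
    subject.ep_table = generate_ep_table(truth, spec.ep_model, rng)
    return subject


def generate_cohort(
    spec: CohortSpec,
    outdir: str | Path | None = None,
    eval_options=None,
) -> list[SubjectDataset]:
    """Generate the full cohort (native space, each subject carrying its
    normative deformation field); optionally persist to a manifest layout."""
    rows = _table_rows(spec)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    subjects = [
        generate_subject(spec, i, rows.iloc[i], children[i], eval_options)
        for i in range(spec.n_subjects)
    ]
    if outdir is not None:
        from .anatomy import save_subject

        outdir = Path(outdir)
        manifest = []
        for s in subjects:
            save_subject(s, outdir / s.subject_id)
            manifest.append(str(Path(s.subject_id) / "manifest.json"))
        (outdir / "cohort.json").write_text(
            pd.Series(manifest).to_json(orient="values", indent=1)
        )
    return subjects
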