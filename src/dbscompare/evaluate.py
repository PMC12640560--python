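"""Evaluation harness: run the six model variants over a cohort and compare
them with the statistical machinery used for the in-vivo validation —
per-subject R^2 between predicted activation and evoked-potential amplitude,
paired Wilcoxon signed-rank tests across subjects (exact small-sample
distribution), presence/absence F-scores for the side-effect pathway, and
grouping by directional vs non-directional settings.

The six variants cross {DF, VTA} x {native, normative} x {pathway,
structure}; (DF, structure) is inadmissible because the driving-force
predictor is defined on axonal trajectories.  Structure representation maps
the therapeutic construct HDP -> STN and the side-effect construct
CSBT -> internal capsule; the structure metric is voxel overlap in
normative space and mesh-vertex overlap in native space, mirroring the two
software pipelines being emulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .anatomy import SubjectDataset, apply_warp, warp_placement
from .fields import (
    CircuitParams,
    FieldSolution,
    SolverOptions,
    VolumeConductor,
    df_conductivity,
    efield_magnitude,
    lead_frame_grid,
    vta_conductivity,
    world_grid_for_lead,
)
from .leads import LeadPlacement, StimSetting, build_lead, world_to_lead
from .predictors import (
    ExcitationParams,
    VTAVolume,
    build_vta,
    internodal_length_mm,
    _node_drive_curve,
    points_to_voxels,
    resample_polyline,
)

__all__ = [
    "VariantSpec",
    "EvalOptions",
    "ComparisonReport",
    "six_variants",
    "default_contrasts",
    "r_squared",
    "wilcoxon_signed_rank",
    "f_score_presence",
    "run_variant",
    "run_cohort",
    "compare_variants",
    "VariantRunner",
]

PATHWAY_TO_STRUCTURE = {"HDP": "STN", "CSBT": "IC"}


@dataclass(frozen=True)
class VariantSpec:
    method: str  # "DF" | "VTA"
    space: str  # "native" | "normative"
    representation: str  # "pathway" | "structure"

    def __post_init__(self) -> None:
        if self.method not in ("DF", "VTA"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.space not in ("native", "normative"):
            raise ValueError(f"unknown space {self.space!r}")
        if self.representation not in ("pathway", "structure"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.method == "DF" and self.representation == "structure":
            raise ValueError("the DF predictor only models pathway activation")

    @property
    def key(self) -> str:
        return f"{self.method}-{self.space.capitalize()}-{self.representation.capitalize()}"

    @classmethod
    def parse(cls, key: str) -> "VariantSpec":
        m, s, r = key.split("-")
        return cls(m.upper(), s.lower(), r.lower())

    def __str__(self) -> str:
        return self.key


def six_variants() -> list[VariantSpec]:
    out = []
    for m in ("DF", "VTA"):
        for s in ("native", "normative"):
            for r in ("pathway", "structure"):
                if m == "DF" and r == "structure":
                    continue
                out.append(VariantSpec(m, s, r))
    return out


def default_contrasts() -> list[tuple[str, str]]:
    """Paired comparisons: every variant against the reference
    (DF-Native-Pathway) plus all single-factor pairs."""
    ref = VariantSpec("DF", "native", "pathway")
    variants = six_variants()
    pairs: list[tuple[str, str]] = []
    seen = set()

    def add(a: VariantSpec, b: VariantSpec) -> None:
        k = tuple(sorted((a.key, b.key)))
        if k not in seen:
            seen.add(k)
            pairs.append((a.key, b.key))

    for v in variants:
        if v != ref:
            add(ref, v)
    for a in variants:
        for b in variants:
            if a.key < b.key:
                diff = sum(
                    getattr(a, f) != getattr(b, f) for f in ("method", "space", "representation")
                )
                if diff == 1:
                    add(a, b)
    return pairs


@dataclass(frozen=True)
class EvalOptions:
    df_solver: SolverOptions = field(default_factory=lambda: SolverOptions(spacing=0.5, padding=8.0))
    vta_solver: SolverOptions = field(default_factory=lambda: SolverOptions(spacing=0.75, padding=8.0))
    vta_threshold: float = 0.2  # V/mm
    sigma_tissue: float = 0.2
    sigma_scar: float = 0.07
    scar_thickness: float = 0.5
    sigma_gray: float = 0.33
    sigma_white: float = 0.14
    excitation: ExcitationParams = field(default_factory=ExcitationParams)
    circuit: CircuitParams = field(default_factory=CircuitParams)
    apply_temporal_scale: bool = True
    dense_step: float = 0.1  # mm, fiber arc sampling for DF


# ---------------------------------------------------------------------------
# Statistics


def r_squared(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Square of the Pearson correlation between prediction and observation.

    Returns ``nan`` when either series is constant (undefined; the subject is
    excluded from that contrast by the caller).
    """
    x = np.asarray(predicted, float)
    y = np.asarray(observed, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _exact_signed_rank_counts(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Distribution of 2*W+ over all sign assignments: returns (counts, T)
    where counts[w] = #assignments with doubled positive-rank sum w, T = max."""
    r2 = np.round(2.0 * ranks).astype(np.int64)  # midranks -> integers
    T = int(r2.sum())
    c = np.zeros(T + 1)
    c[0] = 1.0
    for r in r2:
        c[r:] = c[r:] + c[: T + 1 - r]
    return c, T


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    alternative: str = "two-sided",
    exact_limit: int = 25,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired data (or differences if ``y`` is
    None): zero differences dropped, midranks for ties, exact distribution by
    enumeration over sign assignments for n <= ``exact_limit``, normal
    approximation (tie-corrected, continuity-corrected) beyond.

    Returns (W+, p).
    """
    d = np.asarray(x, float) - (np.asarray(y, float) if y is not None else 0.0)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    if n < 5:
        warnings.warn(f"only {n} nonzero differences; test is very low powered", stacklevel=2)
    ranks = rankdata(np.abs(d))
    wplus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        counts, T = _exact_signed_rank_counts(ranks)
        total = 2.0**n
        w2 = int(round(2.0 * wplus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return wplus, float(p)
    # normal approximation
    mu = n * (n + 1) / 4.0
    _, t = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (t**3 - t).sum() / 48.0
    from scipy.stats import norm

    sd = np.sqrt(var)
    if alternative == "greater":
        p = norm.sf((wplus - 0.5 - mu) / sd)
    elif alternative == "less":
        p = norm.cdf((wplus + 0.5 - mu) / sd)
    else:
        z = (wplus - mu - np.sign(wplus - mu) * 0.5) / sd
        p = 2.0 * norm.sf(abs(z))
    return wplus, float(min(p, 1.0))


def f_score_presence(predicted: np.ndarray, observed: np.ndarray) -> float | None:
    """F-score on presence/absence of activation (strict > 0 binarization).

    Returns ``None`` (excluded) when the observed series is all zero — the
    exclusion rule for subjects with no detectable side-effect response.
    With observed positives but no predicted true positives the score is 0.
    """
    p = np.asarray(predicted, float) > 0.0
    o = np.asarray(observed, float) > 0.0
    if not o.any():
        return None
    tp = int((p & o).sum())
    fp = int((p & ~o).sum())
    fn = int((~p & o).sum())
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return float(2.0 * precision * recall / (precision + recall))


# ---------------------------------------------------------------------------
# Variant execution

_DF_CONDUCTOR_CACHE: dict[tuple, VolumeConductor] = {}


def _df_conductor(lead_name: str, options: EvalOptions) -> VolumeConductor:
    key = (
        lead_name,
        options.df_solver.spacing,
        options.df_solver.padding,
        options.df_solver.sigma_metal,
        options.df_solver.sigma_insulator,
        options.sigma_tissue,
        options.sigma_scar,
        options.scar_thickness,
    )
    if key not in _DF_CONDUCTOR_CACHE:
        lead = build_lead(lead_name)
        grid = lead_frame_grid(lead, options.df_solver)
        cond = df_conductivity(
            lead,
            grid,
            sigma_tissue=options.sigma_tissue,
            sigma_scar=options.sigma_scar,
            scar_thickness=options.scar_thickness,
            options=options.df_solver,
        )
        _DF_CONDUCTOR_CACHE[key] = VolumeConductor(cond, options.df_solver)
    return _DF_CONDUCTOR_CACHE[key]


def _config_key(s: StimSetting) -> tuple:
    return (s.cathodes, s.anodes)


def _unit_currents(s: StimSetting) -> dict[int, float]:
    """Per-contact current for a 1 mA setting (cathodes negative)."""
    out = {c: -1.0 / len(s.cathodes) for c in s.cathodes}
    for a in s.anodes:
        out[a] = 1.0 / len(s.anodes)
    return out


class _SpaceGeometry:
    def __init__(self, subject: SubjectDataset, space: str):
        if space == "native":
            self.placement = subject.placement
            self.structures = subject.structures
            self.pathways = subject.pathways
        else:
            if subject.deformation is None:
                raise ValueError(f"subject {subject.subject_id} has no deformation field")
            warp = subject.deformation
            lead = build_lead(subject.lead_name)
            self.placement, self.restraighten_residual = warp_placement(lead, subject.placement, warp)
            self.structures = {n: apply_warp(s, warp) for n, s in subject.structures.items()}
            self.pathways = {n: apply_warp(p, warp) for n, p in subject.pathways.items()}


class VariantRunner:
    """Executes model variants for one subject, sharing field solutions and
    sampled geometry across variants."""

    def __init__(self, subject: SubjectDataset, options: EvalOptions | None = None):
        self.subject = subject
        self.options = options or EvalOptions()
        self.lead = build_lead(subject.lead_name)
        self._spaces: dict[str, _SpaceGeometry] = {}
        self._df_drives: dict[str, dict] = {}
        self._vta: dict[str, dict] = {}

    def space(self, space: str) -> _SpaceGeometry:
        if space not in self._spaces:
            self._spaces[space] = _SpaceGeometry(self.subject, space)
        return self._spaces[space]

    # -- DF branch ---------------------------------------------------------

    def _df_context(self, space: str) -> dict:
        if space not in self._df_drives:
            geo = self.space(space)
            vc = _df_conductor(self.subject.lead_name, self.options)
            grid = vc.grid
            ctx: dict = {"configs": {}}
            used = sorted({c for s in self.subject.settings for c in s.active_contacts})
            for name, pw in geo.pathways.items():
                dense = [resample_polyline(f, self.options.dense_step) for f in pw.streamlines]
                arcs = [np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(f, axis=0), axis=1))]) for f in dense]
                pts_lead = world_to_lead(np.concatenate(dense), geo.placement)
                vox = grid.world_to_voxel(pts_lead)
                from scipy.ndimage import map_coordinates

                samples = {
                    c: map_coordinates(vc.unit_solution(c), vox.T, order=1, mode="nearest")
                    for c in used
                }
                offsets = np.cumsum([0] + [len(f) for f in dense])
                ctx[name] = {
                    "arcs": arcs,
                    "samples": samples,
                    "offsets": offsets,
                    "L": internodal_length_mm(pw.fiber_diameter_um),
                }
            self._df_drives[space] = ctx
        return self._df_drives[space]

    def _df_config_drives(self, space: str, setting: StimSetting, pathway: str) -> np.ndarray:
        """Peak depolarizing drive per fiber (V per mA) for a contact
        configuration."""
        ctx = self._df_context(space)
        key = (_config_key(setting), pathway)
        if key not in ctx["configs"]:
            p = ctx[pathway]
            currents = _unit_currents(setting)
            vals = np.zeros(p["offsets"][-1])
            for c, i_mA in currents.items():
                vals += i_mA * p["samples"][c]
            drives = np.empty(len(p["arcs"]))
            for i, s in enumerate(p["arcs"]):
                v = vals[p["offsets"][i] : p["offsets"][i + 1]]
                drives[i] = _node_drive_curve(v, s, p["L"], self.options.excitation.n_phases)
            ctx["configs"][key] = drives
        return ctx["configs"][key]

    def _df_percent(self, space: str, setting: StimSetting, pathway: str) -> float:
        drives = self._df_config_drives(space, setting, pathway)
        scale = (
            self.options.circuit.scale(setting.pulse_width_us)
            if self.options.apply_temporal_scale
            else 1.0
        )
        k = self.options.excitation.k(setting.pulse_width_us)
        with np.errstate(divide="ignore", invalid="ignore"):
            thresholds = np.where(drives > 0, k / (drives * scale), np.inf)
        return 100.0 * float(np.mean(thresholds < setting.amplitude_mA))

    # -- VTA branch --------------------------------------------------------

    def _vta_context(self, space: str) -> dict:
        if space not in self._vta:
            geo = self.space(space)
            opts = self.options
            grid = world_grid_for_lead(self.lead, geo.placement, opts.vta_solver)
            gray = geo.structures.get("gray")
            gray_mask = gray.resample_to_grid(grid) if gray is not None else None
            cond = vta_conductivity(
                self.lead,
                grid,
                gray_mask=gray_mask,
                placement=geo.placement,
                sigma_gray=opts.sigma_gray,
                sigma_white=opts.sigma_white,
                options=opts.vta_solver,
            )
            vc = VolumeConductor(cond, opts.vta_solver)
            ctx: dict = {"vc": vc, "grid": grid, "cond": cond, "configs": {}}
            shape = np.asarray(grid.shape)
            # pathway representation: per-fiber voxel indices (any-point rule)
            for name, pw in geo.pathways.items():
                idx_per_fiber = []
                for f in pw.streamlines:
                    pts = resample_polyline(f, grid.spacing)
                    ijk = points_to_voxels(pts, grid)
                    ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
                    idx_per_fiber.append(
                        np.unique(np.ravel_multi_index(tuple(ijk[ok].T), grid.shape))
                        if ok.any()
                        else np.empty(0, np.int64)
                    )
                ctx[("fibers", name)] = idx_per_fiber
            # structure representation: voxel indices (normative metric) and
            # mesh-vertex voxel indices (native metric)
            for pname, sname in PATHWAY_TO_STRUCTURE.items():
                st = geo.structures.get(sname)
                if st is None:
                    continue
                smask = st.resample_to_grid(grid)
                ctx[("voxels", sname)] = np.flatnonzero(smask.reshape(-1))
                verts, _ = st.surface_mesh()
                ijk = points_to_voxels(verts, grid)
                ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
                vin = np.full(len(verts), -1, np.int64)
                vin[ok] = np.ravel_multi_index(tuple(ijk[ok].T), grid.shape)
                ctx[("vertices", sname)] = vin
            self._vta[space] = ctx
        return self._vta[space]

    def _vta_mask(self, space: str, setting: StimSetting) -> VTAVolume:
        ctx = self._vta_context(space)
        key = _config_key(setting)
        if key not in ctx["configs"]:
            vc: VolumeConductor = ctx["vc"]
            phi = np.zeros(ctx["grid"].shape)
            for c, i_mA in _unit_currents(setting).items():
                phi += i_mA * vc.unit_solution(c)
            ctx["configs"][key] = (phi, efield_magnitude(phi, ctx["grid"].spacing))
        phi_unit, e_unit = ctx["configs"][key]
        sol = FieldSolution(
            grid=ctx["grid"],
            potential=phi_unit * setting.amplitude_mA,
            conductivity=ctx["cond"],
            contact_currents_mA=setting.contact_currents_mA,
            _efield=e_unit * setting.amplitude_mA,
        )
        return build_vta(sol, self.options.vta_threshold, setting)

    def _vta_value(self, space: str, setting: StimSetting, pathway: str, representation: str) -> float:
        ctx = self._vta_context(space)
        vta = self._vta_mask(space, setting)
        flat = vta.mask.reshape(-1)
        if representation == "pathway":
            fibers = ctx[("fibers", pathway)]
            hits = sum(1 for idx in fibers if idx.size and flat[idx].any())
            return 100.0 * hits / len(fibers)
        sname = PATHWAY_TO_STRUCTURE[pathway]
        if space == "normative":  # voxel-overlap metric
            sidx = ctx[("voxels", sname)]
            if sidx.size == 0:
                raise ValueError(f"structure {sname} empty on the VTA lattice")
            return 100.0 * float(flat[sidx].sum()) / sidx.size
        vin = ctx[("vertices", sname)]  # native: mesh-vertex metric
        inside = np.zeros(vin.size, bool)
        ok = vin >= 0
        inside[ok] = flat[vin[ok]]
        return 100.0 * float(inside.mean())

    # -- public ------------------------------------------------------------

    def run(self, variant: VariantSpec) -> pd.DataFrame:
        if variant.representation == "structure":
            geo = self.space(variant.space)
            for sname in PATHWAY_TO_STRUCTURE.values():
                if sname not in geo.structures:
                    raise ValueError(f"structure {sname!r} missing for {variant.key}")
        rows = []
        for s in self.subject.settings:
            for pathway in ("HDP", "CSBT"):
                if variant.method == "DF":
                    value = self._df_percent(variant.space, s, pathway)
                    kind = "pct_fibers_df"
                elif variant.representation == "pathway":
                    value = self._vta_value(variant.space, s, pathway, "pathway")
                    kind = "pct_fibers_vta"
                else:
                    value = self._vta_value(variant.space, s, pathway, "structure")
                    kind = "pct_structure_voxels" if variant.space == "normative" else "pct_structure_vertices"
                rows.append(
                    (self.subject.subject_id, variant.key, s.setting_id, s.directional, pathway, kind, value)
                )
        return pd.DataFrame(
            rows,
            columns=["subject", "variant", "setting_id", "directional", "pathway", "metric_kind", "value"],
        )


def run_variant(
    subject: SubjectDataset,
    variant: VariantSpec,
    options: EvalOptions | None = None,
    runner: VariantRunner | None = None,
) -> pd.DataFrame:
    """Per-setting activation values for one subject under one variant."""
    r = runner if runner is not None else VariantRunner(subject, options)
    return r.run(variant)


def run_cohort(
    subjects: Iterable[SubjectDataset],
    variants: Sequence[VariantSpec] | None = None,
    options: EvalOptions | None = None,
) -> pd.DataFrame:
    """Activation table for all (subject, variant) pairs; field solutions and
    sampled geometry are shared across variants within a subject."""
    variants = list(variants) if variants is not None else six_variants()
    frames = []
    for subj in subjects:
        runner = VariantRunner(subj, options)
        for v in variants:
            frames.append(runner.run(v))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Comparison report

_EP_COLUMN = {"HDP": "EP1_uV", "CSBT": "EP0_uV"}


@dataclass
class ComparisonReport:
    r2: pd.DataFrame  # variant, pathway, group, subject, r2
    summary: pd.DataFrame  # variant, pathway, group, median, q1, q3, n
    contrasts: pd.DataFrame  # variant_a, variant_b, pathway, group, n_pairs, statistic, p
    fscore: pd.DataFrame  # variant, subject, f_score (NaN = excluded)
    excluded_subjects: dict

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.r2.to_csv(outdir / "r2_per_subject.csv", index=False)
        self.summary.to_csv(outdir / "r2_summary.csv", index=False)
        self.contrasts.to_csv(outdir / "contrasts.csv", index=False)
        self.fscore.to_csv(outdir / "fscore_csbt.csv", index=False)
        import json

        summary = {
            "medians": {
                f"{r.variant}|{r.pathway}|{r.group}": r.median for r in self.summary.itertuples()
            },
            "contrast_p": {
                f"{r.variant_a} vs {r.variant_b}|{r.pathway}|{r.group}": r.p_value
                for r in self.contrasts.itertuples()
            },
            "excluded_subjects": self.excluded_subjects,
        }
        (outdir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


def _group_filter(df: pd.DataFrame, group: str) -> pd.DataFrame:
    if group == "directional":
        return df[df["directional"]]
    if group == "non-directional":
        return df[~df["directional"]]
    return df


def compare_variants(
    subjects: Sequence[SubjectDataset],
    activations: pd.DataFrame,
    variants: Sequence[str] | None = None,
    contrasts: Sequence[tuple[str, str]] | str = "default",
    groups: Sequence[str] = ("all",),
    alternative: str = "two-sided",
) -> ComparisonReport:
    """Build the full comparison report from an activation table
    (as produced by :func:`run_cohort`) and the subjects' EP tables."""
    ep = {s.subject_id: s.ep_table.set_index("setting_id") for s in subjects}
    if variants is None:
        variants = sorted(activations["variant"].unique())
    if contrasts == "default":
        contrasts = [c for c in default_contrasts() if c[0] in variants and c[1] in variants]
    else:
        missing = {v for pair in contrasts for v in pair} - set(variants)
        if missing:
            raise ValueError(f"contrasts reference absent variants: {sorted(missing)}")

    r2_rows = []
    f_rows = []
    excluded: dict[str, list] = {"constant_series": [], "all_zero_ep0": []}
    for variant in variants:
        va = activations[activations["variant"] == variant]
        for group in groups:
            vg = _group_filter(va, group)
            for subj_id, sdf in vg.groupby("subject"):
                for pathway in ("HDP", "CSBT"):
                    p = sdf[sdf["pathway"] == pathway].set_index("setting_id")["value"]
                    obs = ep[subj_id].loc[p.index, _EP_COLUMN[pathway]].to_numpy()
                    if len(p) < 3:
                        continue
                    r2 = r_squared(p.to_numpy(), obs)
                    if np.isnan(r2):
                        excluded["constant_series"].append(
                            {"subject": subj_id, "variant": variant, "pathway": pathway, "group": group}
                        )
                    r2_rows.append((variant, pathway, group, subj_id, r2))
                    if pathway == "CSBT" and group == "all":
                        f = f_score_presence(p.to_numpy(), obs)
                        if f is None:
                            if subj_id not in excluded["all_zero_ep0"]:
                                excluded["all_zero_ep0"].append(subj_id)
                            f_rows.append((variant, subj_id, np.nan))
                        else:
                            f_rows.append((variant, subj_id, f))
    r2_df = pd.DataFrame(r2_rows, columns=["variant", "pathway", "group", "subject", "r2"])
    f_df = pd.DataFrame(f_rows, columns=["variant", "subject", "f_score"])

    sum_rows = []
    for (variant, pathway, group), g in r2_df.groupby(["variant", "pathway", "group"]):
        vals = g["r2"].dropna().to_numpy()
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear-interpolation quantiles
        sum_rows.append((variant, pathway, group, med, q1, q3, vals.size))
    summary = pd.DataFrame(
        sum_rows, columns=["variant", "pathway", "group", "median", "q1", "q3", "n"]
    )

    c_rows = []
    for a, b in contrasts:
        for group in groups:
            for pathway in ("HDP", "CSBT"):
                ga = r2_df.query("variant == @a and pathway == @pathway and group == @group")
                gb = r2_df.query("variant == @b and pathway == @pathway and group == @group")
                merged = ga.merge(gb, on="subject", suffixes=("_a", "_b")).dropna(
                    subset=["r2_a", "r2_b"]
                )
                if len(merged) == 0:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    stat, p = wilcoxon_signed_rank(
                        merged["r2_a"].to_numpy(), merged["r2_b"].to_numpy(), alternative
                    )
                c_rows.append(
                    (
                        a,
                        b,
                        pathway,
                        group,
                        len(merged),
                        stat,
                        p,
                        float(np.median(merged["r2_a"])),
                        float(np.median(merged["r2_b"])),
                    )
                )
    contrasts_df = pd.DataFrame(
        c_rows,
        columns=[
            "variant_a",
            "variant_b",
            "pathway",
            "group",
            "n_pairs",
            "statistic",
            "p_value",
            "median_a",
            "median_b",
        ],
    )
    return ComparisonReport(r2_df, summary, contrasts_df, f_df, excluded)


def plot_r2_boxes(report: ComparisonReport, pathway: str, outfile: str | Path, group: str = "all") -> None:
    """Box plots of per-subject R^2 by variant (one pathway)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.r2.query("pathway == @pathway and group == @group")
    variants = sorted(df["variant"].unique())
    data = [df[df["variant"] == v]["r2"].dropna().to_numpy() for v in variants]
    fig, ax = plt.subplots(figsize=(1.6 * len(variants) + 1, 4))
    ax.boxplot(data, tick_labels=variants)
    ax.set_ylabel(r"per-subject $R^2$")
    ax.set_title(f"{pathway} ({group} settings)")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(outfile, dpi=120)
    plt.close(fig)
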