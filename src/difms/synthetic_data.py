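"""Synthetic direct-infusion FT-ICR experiments with known ground truth.

Emulates the statistical structure the downstream pipeline assumes: a
6-group factorial starvation design (pre-experimental t0 at two
acclimation temperatures; post-experimental t5 at 2 temperatures × 2 pCO2
levels, 10 biological replicates each, plus pooled QC samples), overlapping
SIM windows (seven wide windows over m/z 70–590 for the polar extract;
100–187.5 Da windows over m/z 120–1200 for the nonpolar extract), three
technical replicates per sample, ppm-scale mass error, multiplicative
intensity noise, per-sample log-normal dilution, hard-threshold dropout,
and adduct/isotopologue structure including Li+ adducts with their 6Li
partners.

The default effect model encodes the study outcome being emulated: a
strong time-point (starvation) effect on a named subset of metabolites with
directions matching the observed polar/nonpolar changes, and null
temperature and CO2 effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate as ann
from .constants import (C13_C12_DELTA, C13_C12_RATIO, LI6_LI7_RATIO,
                        LI7_LI6_DELTA)
from .spectra_io import FeatureMatrix, PeakList, peaklist_filename, \
    write_design, write_peaklist

GROUPS = ["t0-8C", "t0-10C", "t5-8C-amb", "t5-8C-1000",
          "t5-10C-amb", "t5-10C-1000"]


def parse_group(group: str) -> dict:
    """Decode a group label into timepoint / temperature / pCO2 metadata."""
    parts = group.split("-")
    timepoint = parts[0]
    temperature = int(parts[1].rstrip("C"))
    pco2 = 1000 if (len(parts) > 2 and parts[2] == "1000") else 380
    return {"timepoint": timepoint, "temperature": temperature, "pco2": pco2}


@dataclass
class MetaboliteSpec:
    name: str
    formula: ann.Formula
    base_intensity: float
    extract: str                              # "polar" | "nonpolar"
    adducts: list[tuple[str, float]] = field(
        default_factory=lambda: [("M+H", 1.0)])

    def __post_init__(self):
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be > 0")
        if self.extract not in ("polar", "nonpolar"):
            raise ValueError(f"unknown extract {self.extract!r}")
        if any(n < 0 for n in self.formula.values()):
            raise ValueError("element counts must be >= 0")
        total_yield = sum(y for _, y in self.adducts)
        if not 0 < total_yield <= 1 + 1e-9:
            raise ValueError("adduct yields must be in (0, 1] and sum <= 1")


@dataclass
class EffectModel:
    timepoint_log2fc: dict[str, float] = field(default_factory=dict)
    temperature_log2fc: dict[str, float] = field(default_factory=dict)
    co2_log2fc: dict[str, float] = field(default_factory=dict)
    intensity_cv: float = 0.2        # multiplicative noise CV per measurement
    dilution_sd: float = 0.3         # SD of log dilution factor (median 1)
    dropout_threshold: float = 2000  # peaks below this intensity are omitted

    def __post_init__(self):
        if self.intensity_cv < 0 or self.dilution_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class AcquisitionConfig:
    windows: list[tuple[float, float]]
    overlap: float = 10.0
    ppm_error_sd: float = 0.5
    n_tech_reps: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_tech_reps < 1:
            raise ValueError("n_tech_reps must be >= 1")
        lows = [w[0] for w in self.windows]
        if lows != sorted(lows):
            raise ValueError("windows must be sorted by lower bound")
        for lo, hi in self.windows:
            if hi <= lo:
                raise ValueError(f"invalid window ({lo}, {hi})")
        for (_, a_hi), (b_lo, _) in zip(self.windows, self.windows[1:]):
            if a_hi - b_lo < self.overlap - 1e-9:
                raise ValueError("adjacent windows must overlap by >= overlap")


def polar_windows(n: int = 7, lo: float = 70.0, hi: float = 590.0,
                  overlap: float = 10.0) -> list[tuple[float, float]]:
    """Seven equal wide-SIM windows tiling m/z 70–590 with fixed overlap."""
    width = (hi - lo + (n - 1) * overlap) / n
    return [(lo + i * (width - overlap), lo + i * (width - overlap) + width)
            for i in range(n)]


def nonpolar_windows(n: int = 8, lo: float = 120.0, hi: float = 1200.0,
                     overlap: float = 10.0) -> list[tuple[float, float]]:
    """Increasing-width SIM windows (linear ramp) tiling m/z 120–1200."""
    span = hi - lo + (n - 1) * overlap
    # widths grow linearly from w0; sum of widths must equal the span
    w0 = 100.0
    wn = 2 * span / n - w0
    widths = np.linspace(w0, wn, n)
    wins = []
    start = lo
    for w in widths:
        wins.append((start, start + w))
        start += w - overlap
    return wins


# Metabolites whose time-point direction is pinned by the study outcome
# (negative: lower after 5 days of starvation; positive: higher).
TIMEPOINT_DIRECTIONS: dict[str, int] = {
    "glycine": -1, "arginine": -1, "histidine": -1, "glutamine": -1,
    "taurine": -1, "carnitine": -1, "oxaloacetate": -1,
    "aspartate": +1, "methionine": +1, "tryptophan": +1,
    "trimethyllysine": +1,
    "FA 20:5 (EPA)": -1, "FA 22:6 (DHA)": -1,
    "FA 20:1 (gondoic acid)": +1, "FA 22:1 (cetoleic acid)": +1,
    "taurolipid TL(20:5)": -1, "taurolipid TL(22:6)": -1,
    "taurolipid TL(20:1)": +1,
    "LPE(20:5)": -1, "LPE(22:6)": -1,
}


def _spec(name: str, formula: str, base: float, extract: str,
          adducts: list[tuple[str, float]]) -> MetaboliteSpec:
    return MetaboliteSpec(name, ann.parse_formula(formula), base, extract, adducts)


def default_library() -> list[MetaboliteSpec]:
    """Packaged metabolite library: the named study metabolites plus
    unaffected fillers; polar amino acids/derivatives and nonpolar free
    fatty acids, taurine lipids and phospholipids."""
    ph = [("M+H", 0.8), ("M+Na", 0.15)]
    li = [("M+H", 0.65), ("M+Na", 0.1), ("M+Li", 0.25)]
    nl = [("M+H", 0.7), ("M+Na", 0.2)]
    polar = [
        _spec("glycine", "C2H5NO2", 8e5, "polar", ph),
        _spec("arginine", "C6H14N4O2", 6e5, "polar", ph),
        _spec("histidine", "C6H9N3O2", 2e5, "polar", ph),
        _spec("glutamine", "C5H10N2O3", 1.5e5, "polar", ph),
        _spec("aspartate", "C4H7NO4", 1e5, "polar", ph),
        _spec("methionine", "C5H11NO2S", 8e4, "polar", ph),
        _spec("tryptophan", "C11H12N2O2", 6e4, "polar", ph),
        _spec("taurine", "C2H7NO3S", 5e5, "polar", ph),
        _spec("trimethyllysine", "C9H20N2O2", 1.2e5, "polar", ph),
        _spec("carnitine", "C7H15NO3", 2.5e5, "polar", ph),
        _spec("oxaloacetate", "C4H4O5", 5e4, "polar", ph),
        _spec("alanine", "C3H7NO2", 3e5, "polar", ph),
        _spec("proline", "C5H9NO2", 2e5, "polar", ph),
        _spec("glutamate", "C5H9NO4", 2.5e5, "polar", ph),
        _spec("lactate", "C3H6O3", 1.8e5, "polar", li),
        _spec("betaine", "C5H11NO2", 4e5, "polar", li),
        _spec("choline", "C5H13NO", 3e5, "polar", ph),
        _spec("serine", "C3H7NO3", 1.2e5, "polar", ph),
        _spec("lysine", "C6H14N2O2", 1.5e5, "polar", ph),
    ]
    nonpolar = [
        _spec("FA 20:5 (EPA)", "C20H30O2", 6e5, "nonpolar", nl),
        _spec("FA 22:6 (DHA)", "C22H32O2", 5e5, "nonpolar", nl),
        _spec("FA 20:1 (gondoic acid)", "C20H38O2", 4e5, "nonpolar", nl),
        _spec("FA 22:1 (cetoleic acid)", "C22H42O2", 3e5, "nonpolar", nl),
        _spec("FA 16:0 (palmitic acid)", "C16H32O2", 5e5, "nonpolar", nl),
        _spec("FA 18:1 (oleic acid)", "C18H34O2", 4.5e5, "nonpolar", nl),
        _spec("taurolipid TL(20:5)", "C42H67NO5S", 3e5, "nonpolar", nl),
        _spec("taurolipid TL(22:6)", "C44H69NO5S", 2.5e5, "nonpolar", nl),
        _spec("taurolipid TL(20:1)", "C42H75NO5S", 2e5, "nonpolar", nl),
        _spec("LPE(20:5)", "C25H42NO7P", 1.5e5, "nonpolar", nl),
        _spec("LPE(22:6)", "C27H44NO7P", 1.2e5, "nonpolar", nl),
        _spec("sphingosine 1-phosphate", "C18H38NO5P", 1e5, "nonpolar", nl),
        _spec("sphingosylphosphorylcholine", "C23H49N2O5P", 8e4, "nonpolar", nl),
    ]
    return polar + nonpolar


def default_effect_model(library: list[MetaboliteSpec] | None = None,
                         seed: int = 0, **overrides) -> EffectModel:
    """Time-point effects on the named metabolites, null T/CO2 effects.

    |log2 fold change| is drawn once from Uniform(0.5, 2) per affected
    metabolite, signed by the study's observed direction.
    """
    if library is None:
        library = default_library()
    rng = np.random.default_rng(seed)
    names = {m.name for m in library}
    lfc = {}
    for name, sign in TIMEPOINT_DIRECTIONS.items():
        if name in names:
            lfc[name] = sign * rng.uniform(0.5, 2.0)
    return EffectModel(timepoint_log2fc=lfc, **overrides)


def build_design(n_reps: int = 10, groups: list[str] | None = None,
                 n_qc: int = 2) -> pd.DataFrame:
    """One row per (group, replicate), plus pooled QC rows; deterministic order."""
    if groups is None:
        groups = list(GROUPS)
    if not groups:
        raise ValueError("groups must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for g in groups:
        meta = parse_group(g) if g.startswith(("t0", "t5")) else \
            {"timepoint": "", "temperature": np.nan, "pco2": np.nan}
        for r in range(1, n_reps + 1):
            rows.append({"sample_id": f"{g}-r{r:02d}", "group": g,
                         "replicate": r, **meta, "qc": False})
    for q in range(1, n_qc + 1):
        rows.append({"sample_id": f"QC-{q}", "group": "QC", "replicate": q,
                     "timepoint": "", "temperature": np.nan, "pco2": np.nan,
                     "qc": True})
    return pd.DataFrame(rows)


@dataclass
class SyntheticExperiment:
    design: pd.DataFrame
    peaklists: dict[tuple[str, str, str], PeakList]
    truth: pd.DataFrame
    windows: list[tuple[float, float]]
    extract: str

    def replicate_ids(self) -> list[str]:
        return sorted({k[1] for k in self.peaklists})

    def window_ids(self) -> list[str]:
        return sorted({k[2] for k in self.peaklists})


def _group_mean(met: MetaboliteSpec, effects: EffectModel, group: str) -> float:
    meta = parse_group(group)
    lfc = 0.0
    if meta["timepoint"] == "t5":
        lfc += effects.timepoint_log2fc.get(met.name, 0.0)
    if meta["temperature"] == 10:
        lfc += effects.temperature_log2fc.get(met.name, 0.0)
    if meta["pco2"] == 1000:
        lfc += effects.co2_log2fc.get(met.name, 0.0)
    return met.base_intensity * 2.0 ** lfc


def simulate_peaklists(library: list[MetaboliteSpec],
                       effects: EffectModel,
                       acq: AcquisitionConfig,
                       design: pd.DataFrame,
                       extract: str = "polar") -> SyntheticExperiment:
    """Generate per-sample × replicate × window centroided peak lists.

    Each adduct ion of each library metabolite (of the requested extract)
    yields a peak at its theoretical m/z perturbed by Normal ppm error, with
    intensity = group mean × sample dilution × measurement noise; 13C and
    (for Li+ adducts) 6Li isotopologues are emitted at natural-abundance
    ratios; peaks below the dropout threshold are omitted. QC samples are
    generated from the pooled mean of all biological samples. One seeded
    RNG stream drives the whole experiment.
    """
    rng = np.random.default_rng(acq.seed)
    mets = [m for m in library if m.extract == extract]
    lo_all = min(w[0] for w in acq.windows)
    hi_all = max(w[1] for w in acq.windows)

    # theoretical ion table: (metabolite, ion label, mz, relative yield)
    ions: list[tuple[MetaboliteSpec, str, float, float]] = []
    excluded: set[str] = set()
    for met in mets:
        in_any = False
        for ad_name, ad_yield in met.adducts:
            adduct = ann.ADDUCTS_BY_NAME[ad_name]
            mz = ann.adduct_mz(met.formula, adduct)
            if not any(lo <= mz <= hi for lo, hi in acq.windows):
                continue
            in_any = True
            ions.append((met, ad_name, mz, ad_yield))
            n_c = met.formula.get("C", 0)
            if n_c:
                ions.append((met, ad_name + "+13C",
                             mz + C13_C12_DELTA / adduct.charge,
                             ad_yield * n_c * C13_C12_RATIO))
            if adduct.added.get("Li", 0):
                ions.append((met, ad_name + "+6Li",
                             mz - LI7_LI6_DELTA / adduct.charge,
                             ad_yield * LI6_LI7_RATIO))
        if not in_any:
            warnings.warn(f"metabolite {met.name!r} has no adduct inside "
                          f"[{lo_all:g}, {hi_all:g}]; excluded", stacklevel=2)
            excluded.add(met.name)

    bio = design[~design["qc"]]
    groups = list(dict.fromkeys(bio["group"]))
    group_means = {m.name: {g: _group_mean(m, effects, g) for g in groups}
                   for m in mets}
    # per-sample dilution factors (log-normal, median 1)
    dilution = {sid: float(np.exp(rng.normal(0.0, effects.dilution_sd)))
                if effects.dilution_sd > 0 else 1.0
                for sid in bio["sample_id"]}
    # pooled QC level per metabolite: mean over biological samples
    qc_level = {m.name: float(np.mean([group_means[m.name][g] * dilution[s]
                                       for s, g in zip(bio["sample_id"],
                                                       bio["group"])]))
                for m in mets}

    cv = effects.intensity_cv
    sigma = float(np.sqrt(np.log1p(cv ** 2))) if cv > 0 else 0.0
    mu = -sigma ** 2 / 2  # unit-mean log-normal noise

    peaklists: dict[tuple[str, str, str], PeakList] = {}
    window_ids = [f"w{i:02d}" for i in range(len(acq.windows))]
    for _, row in design.iterrows():
        sid, grp, is_qc = row["sample_id"], row["group"], bool(row["qc"])
        for r in range(1, acq.n_tech_reps + 1):
            rid = f"tr{r}"
            for win_id, (w_lo, w_hi) in zip(window_ids, acq.windows):
                mzs, ints = [], []
                for met, _ion, mz, rel_yield in ions:
                    if met.name in excluded or not w_lo <= mz <= w_hi:
                        continue
                    if is_qc:
                        level = qc_level[met.name]
                    else:
                        level = group_means[met.name][grp] * dilution[sid]
                    noise = float(np.exp(rng.normal(mu, sigma))) if sigma else 1.0
                    intensity = level * rel_yield * noise
                    eps = rng.normal(0.0, acq.ppm_error_sd * 1e-6) \
                        if acq.ppm_error_sd > 0 else 0.0
                    if intensity < effects.dropout_threshold:
                        continue
                    mzs.append(mz * (1.0 + eps))
                    ints.append(intensity)
                peaklists[(sid, rid, win_id)] = PeakList(
                    sid, rid, win_id, np.array(mzs), np.array(ints))

    truth_rows = []
    for met in mets:
        entry = {"metabolite": met.name,
                 "formula": ann.format_formula(met.formula),
                 "extract": met.extract,
                 "affected": met.name in effects.timepoint_log2fc,
                 "timepoint_log2fc": effects.timepoint_log2fc.get(met.name, 0.0),
                 "excluded": met.name in excluded}
        for g in groups:
            entry[f"mean_{g}"] = group_means[met.name][g]
        truth_rows.append(entry)
    truth = pd.DataFrame(truth_rows)
    return SyntheticExperiment(design=design.copy(), peaklists=peaklists,
                               truth=truth, windows=list(acq.windows),
                               extract=extract)


def write_experiment(exp: SyntheticExperiment, outdir) -> None:
    """Write peak-list TSVs plus design.csv and truth.csv under ``outdir``."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_design(exp.design, outdir / "design.csv")
    exp.truth.to_csv(outdir / "truth.csv", index=False)
    for (sid, rid, wid), pl in exp.peaklists.items():
        write_peaklist(pl, outdir / peaklist_filename(sid, rid, wid))


def simulate_intensity_matrix(n_per_class: int = 10, n_features: int = 500,
                              affected_frac: float = 0.2,
                              lfc_low: float = 0.5, lfc_high: float = 2.0,
                              intensity_cv: float = 0.2,
                              dilution_sd: float = 0.0,
                              dropout_threshold: float = 0.0,
                              seed: int = 0
                              ) -> tuple[FeatureMatrix, np.ndarray, pd.DataFrame]:
    """Feature-level shortcut generator for the two-time-point contrast.

    Produces an (already stitched and replicate-filtered) intensity matrix
    of ``n_per_class`` t0 and t5 samples over anonymous features: baselines
    log-uniform over 10^3.5–10^6, an ``affected_frac`` subset shifted at t5
    by |log2 FC| ~ Uniform(lfc_low, lfc_high) with random sign,
    multiplicative log-normal noise of the given CV, optional per-sample
    dilution and hard dropout. Returns (matrix, labels, truth).
    """
    rng = np.random.default_rng(seed)
    base = 10.0 ** rng.uniform(3.5, 6.0, n_features)
    n_affected = int(round(affected_frac * n_features))
    affected = np.zeros(n_features, dtype=bool)
    affected[rng.choice(n_features, n_affected, replace=False)] = True
    lfc = np.zeros(n_features)
    lfc[affected] = (rng.uniform(lfc_low, lfc_high, n_affected)
                     * rng.choice([-1.0, 1.0], n_affected))
    labels = np.array(["t0"] * n_per_class + ["t5"] * n_per_class)
    means = np.where((labels == "t5")[:, None], base * 2.0 ** lfc, base)
    sigma = float(np.sqrt(np.log1p(intensity_cv ** 2))) if intensity_cv else 0.0
    noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma, means.shape)) \
        if sigma else 1.0
    dil = np.exp(rng.normal(0, dilution_sd, (2 * n_per_class, 1))) \
        if dilution_sd else 1.0
    values = means * noise * dil
    if dropout_threshold > 0:
        values = np.where(values < dropout_threshold, np.nan, values)
    sample_ids = [f"{lab}-s{i:02d}" for i, lab in enumerate(labels)]
    fm = FeatureMatrix(sample_ids, np.arange(1, n_features + 1, dtype=float),
                       values)
    truth = pd.DataFrame({"feature": np.arange(n_features),
                          "affected": affected, "log2fc": lfc,
                          "base_intensity": base})
    return fm, labels, truth
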