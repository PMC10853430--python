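"""Synthetic study generator with known ground truth.

Emulates a four-condition continuous-cropping chronosequence (CC1Y, CC3Y,
CC5Y, CC7Y; three replicates each) the way the analysis pipeline sees it:

* per-sample DOM formula populations drawn from configured van Krevelen
  class mixtures (tannins declining 18.13% -> 13.95%, aliphatic/proteins
  rising 2.73% -> 8.85%, lignin/CRAM-like dominant near 55%) and element
  group mixtures (CHON declining, CHOS/CHONS rising),
* negative-mode peak lists over m/z 200-1000 with Gaussian ppm mass
  error, log-normal intensities, a configured fraction of sub-threshold
  S/N peaks, and noise peaks guaranteed unassignable (no valid formula
  within 2 ppm),
* a soil-chemistry table with condition trends (TC/TN/OM decreasing,
  C/N rising late, DOC V-shaped, pH flat),
* a genus relative-abundance table with planted monotone couplings to
  pipeline features, realized through a Gaussian copula so the *true*
  Spearman correlation is exact by construction.

Conditions share class-stratified formula pools, so comparing early and
late conditions yields non-trivial degraded / remaining / produced sets.
The configuration seed fully determines every output.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import AssignmentParams, enumerate_candidates
from .formulas import (
    MASS_C,
    MASS_H,
    MASS_N,
    MASS_O,
    MASS_PROTON,
    MASS_S,
    ElementGroup,
    MolecularFormula,
    mz_from_neutral_mass,
)
from .vankrevelen import (
    DEFAULT_BOUNDARIES,
    SEVEN_CLASSES,
    ClassBox,
    CompoundClass,
    classify_arrays,
)

CONDITIONS: tuple[str, ...] = ("CC1Y", "CC3Y", "CC5Y", "CC7Y")

#: Per-condition compound-class mixtures (percent of formulas).  The
#: tannins and aliphatic/proteins endpoints and the lignin/CRAM share are
#: the study trends being emulated; intermediate conditions interpolate
#: linearly and the minor classes absorb the remainder.
DEFAULT_CLASS_MIXTURES: dict[str, tuple[float, float, float, float]] = {
    "lipids": (4.00, 5.00, 6.00, 7.00),
    "aliphatic_proteins": (2.73, 4.77, 6.81, 8.85),
    "lignin_cram": (56.83, 55.62, 54.41, 53.20),
    "carbohydrates": (3.00, 4.00, 5.00, 6.00),
    "unsaturated_hc": (3.31, 4.21, 5.10, 6.00),
    "condensed_aromatics": (12.00, 9.66, 7.33, 5.00),
    "tannins": (18.13, 16.74, 15.34, 13.95),
}

#: Per-condition element-group mixtures (percent): CHON dominant but
#: declining, S-bearing groups rising with cropping years.
DEFAULT_GROUP_MIXTURES: dict[str, tuple[float, float, float, float]] = {
    "CHO": (36.44, 35.85, 35.25, 34.66),
    "CHON": (52.24, 50.19, 48.15, 46.10),
    "CHOS": (5.81, 7.57, 9.34, 11.10),
    "CHONS": (5.51, 6.39, 7.26, 8.14),
}

#: Soil-chemistry condition means and replicate noise sd.
#: Units: pH unitless; TC, TN, OM g/kg; DOC mg/kg.  C/N is derived per
#: sample as TC/TN (hence rising once TN falls faster than TC).
DEFAULT_CHEMISTRY: dict[str, tuple[tuple[float, float, float, float], float]] = {
    "pH": ((5.60, 5.60, 5.60, 5.60), 0.08),
    "TC": ((12.50, 10.80, 10.20, 9.90), 0.30),
    "TN": ((1.25, 1.10, 0.95, 0.82), 0.03),
    "OM": ((21.00, 18.50, 16.00, 14.00), 0.50),
    "DOC": ((310.0, 255.0, 235.0, 275.0), 8.0),
}


@dataclass(frozen=True, slots=True)
class PlantedCoupling:
    """A genus monotonically coupled to a pipeline feature.

    ``spearman`` is the *true* rank correlation of the underlying
    Gaussian copula (sign included).
    """

    genus: str
    feature: str
    spearman: float


DEFAULT_COUPLINGS: tuple[PlantedCoupling, ...] = (
    PlantedCoupling("Methylobacter", "aliphatic_proteins", 0.95),
    PlantedCoupling("Thiobacillus", "CHOS", 0.95),
    PlantedCoupling("wb1-P19", "TN", 0.95),
    PlantedCoupling("Aquabacterium", "C/N", 0.90),
)

#: Genera structurally absent from some conditions (indices into
#: CONDITIONS), giving the presence/absence Venn stage real signal.
DEFAULT_ABSENCES: dict[str, tuple[int, ...]] = {
    "wb1-P19": (2, 3),
    "Aquabacterium": (0,),
    "Methylobacter": (0, 1),
    "Thiobacillus": (0,),
    "Filler_early_1": (3,),
    "Filler_late_1": (0, 1),
    "Filler_late_2": (0,),
}


class InfeasibleScenarioError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic study.

    The defaults *are* the emulated study conditions: 4 cropping-year
    conditions x 3 replicates, 5000 formulas per sample, m/z 200-1000,
    0.3 ppm mass-error sd, 5% noise peaks, 5% of signal peaks below the
    S/N 4 threshold.
    """

    seed: int = 0
    conditions: tuple[str, ...] = CONDITIONS
    replicates: int = 3
    formulas_per_sample: int = 5000
    class_mixtures: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURES)
    )
    group_mixtures: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MIXTURES)
    )
    mass_window: tuple[float, float] = (200.0, 1000.0)
    mass_error_ppm_sd: float = 0.3
    noise_fraction: float = 0.05
    snr_below_frac: float = 0.05
    #: pool size multiplier: each (class, group) stratum holds
    #: pool_factor x its largest per-sample quota of distinct formulas,
    #: shared across conditions so inventories overlap.
    pool_factor: float = 2.0
    chemistry: dict[str, tuple[tuple[float, ...], float]] = field(
        default_factory=lambda: dict(DEFAULT_CHEMISTRY)
    )
    n_filler_genera: int = 16
    couplings: tuple[PlantedCoupling, ...] = DEFAULT_COUPLINGS
    absences: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ABSENCES)
    )

    def __post_init__(self) -> None:
        k = len(self.conditions)
        for name, mix in (("class_mixtures", self.class_mixtures), ("group_mixtures", self.group_mixtures)):
            for cls, vec in mix.items():
                if len(vec) != k:
                    raise ValueError(f"{name}[{cls!r}] must have {k} entries")
            totals = np.asarray(list(mix.values())).sum(axis=0)
            if not np.allclose(totals, 100.0, atol=0.05):
                raise ValueError(f"{name} columns must each sum to 100%, got {totals}")
        if self.replicates < 1 or self.formulas_per_sample < 1:
            raise ValueError("replicates and formulas_per_sample must be >= 1")
        if not (0 <= self.noise_fraction < 1 and 0 <= self.snr_below_frac < 1):
            raise ValueError("fractions must be in [0, 1)")

    def class_probs(self, cond_index: int) -> np.ndarray:
        v = np.array([self.class_mixtures[c.value][cond_index] for c in SEVEN_CLASSES])
        return v / v.sum()

    def group_probs(self, cond_index: int) -> np.ndarray:
        v = np.array([self.group_mixtures[g.value][cond_index] for g in ElementGroup])
        return v / v.sum()

    def sample_ids(self) -> list[str]:
        return [f"{c}_r{r + 1}" for c in self.conditions for r in range(self.replicates)]

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                k: (sorted(v.items()) if isinstance(v, dict) else v)
                for k, v in self.__dict__.items()
                if k != "couplings"
            }
            | {"couplings": [(c.genus, c.feature, c.spearman) for c in self.couplings]},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# formula sampling

_BOX_BY_CLASS: dict[CompoundClass, ClassBox] = {
    b.compound_class: b for b in DEFAULT_BOUNDARIES
}
_N_CHOICES = np.array([1, 2, 3])
_N_PROBS = np.array([0.5, 0.3, 0.2])


def _draw_n_s(group: ElementGroup, size: int, rng: np.random.Generator):
    if group in (ElementGroup.CHON, ElementGroup.CHONS):
        n = rng.choice(_N_CHOICES, size=size, p=_N_PROBS)
    else:
        n = np.zeros(size, dtype=np.int64)
    s = np.ones(size, dtype=np.int64) if group in (ElementGroup.CHOS, ElementGroup.CHONS) else np.zeros(size, dtype=np.int64)
    return n, s


def sample_formulas_in_class(
    cls: CompoundClass,
    count: int,
    rng: np.random.Generator,
    mass_window: tuple[float, float] = (200.0, 1000.0),
    group: ElementGroup = ElementGroup.CHO,
    margin: float = 0.01,
    params: AssignmentParams | None = None,
    unique: bool = False,
    max_rounds: int = 80,
) -> np.ndarray:
    """Rejection-sample ``count`` formulas strictly inside a class box.

    Returns an (count, 5) int array of (C, H, O, N, S) rows.  Every row
    has exact mass inside ``mass_window``, passes the assignment validity
    screen, keeps (O/C, H/C) at least ``margin`` away from the box edges,
    and classifies back to ``cls`` under the default precedence (boxes
    earlier in precedence can shadow part of a later box; shadowed draws
    are rejected).  With ``unique=True`` the rows are distinct formulas.
    """
    if cls is CompoundClass.UNCLASSIFIED:
        raise ValueError("cannot sample from the unclassified pseudo-class")
    if params is None:
        params = AssignmentParams(mz_min=mass_window[0], mz_max=mass_window[1])
    box = _BOX_BY_CLASS[cls]
    oc_lo_f, oc_hi_f = box.oc_low + margin, box.oc_high - margin
    hc_lo_f, hc_hi_f = box.hc_low + margin, box.hc_high - margin
    acc: list[np.ndarray] = []
    n_acc = 0
    for _ in range(max_rounds):
        if n_acc >= count:
            break
        m = max(4 * (count - n_acc), 256)
        c = rng.integers(6, min(55, params.max_c) + 1, size=m)
        n, s = _draw_n_s(group, m, rng)
        o_lo = np.maximum(1, np.ceil(oc_lo_f * c - 1e-9)).astype(np.int64)
        o_hi = np.minimum(params.max_o, np.floor(oc_hi_f * c + 1e-9)).astype(np.int64)
        h_lo = np.maximum(1, np.ceil(hc_lo_f * c - 1e-9)).astype(np.int64)
        h_hi = np.minimum.reduce(
            [np.full(m, params.max_h), np.floor(hc_hi_f * c + 1e-9).astype(np.int64), 2 * c + n + 2]
        )
        h_lo = h_lo + ((h_lo + n) % 2)  # parity: integer DBE needs H = N (mod 2)
        feasible = (o_lo <= o_hi) & (h_lo <= h_hi)
        span_o = np.where(feasible, o_hi - o_lo + 1, 1)
        span_h = np.where(feasible, (h_hi - h_lo) // 2 + 1, 1)
        o = o_lo + rng.integers(0, span_o)
        h = h_lo + 2 * rng.integers(0, span_h)
        mass = c * MASS_C + h * MASS_H + o * MASS_O + n * MASS_N + s * MASS_S
        ok = (
            feasible
            & (mass >= mass_window[0])
            & (mass <= mass_window[1])
            & (classify_arrays(o / c, h / c) == cls.value)
        )
        if ok.any():
            acc.append(np.stack([c[ok], h[ok], o[ok], n[ok], s[ok]], axis=1))
            if unique:
                merged = np.unique(np.concatenate(acc, axis=0), axis=0)
                acc = [merged]
                n_acc = len(merged)
            else:
                n_acc += int(ok.sum())
    if n_acc < count:
        raise InfeasibleScenarioError(
            f"could not sample {count} formulas in {cls.value}/{group.value} "
            f"within {max_rounds} rounds (got {n_acc})"
        )
    rows = np.concatenate(acc, axis=0)[:count]
    return rows


def sample_formula_in_class(
    cls: CompoundClass,
    mass_window: tuple[float, float],
    rng: np.random.Generator,
    group: ElementGroup = ElementGroup.CHO,
) -> MolecularFormula:
    """Single-draw convenience wrapper around the batch sampler."""
    row = sample_formulas_in_class(cls, 1, rng, mass_window, group)[0]
    return MolecularFormula(*(int(v) for v in row))


# --------------------------------------------------------------------------
# study assembly

@dataclass
class GroundTruth:
    """What was actually generated, sufficient to score any stage."""

    formula_tables: dict[str, pd.DataFrame]  # sample_id -> truth rows
    chemistry_means: pd.DataFrame
    planted_edges: tuple[PlantedCoupling, ...]
    noise_counts: dict[str, int]


@dataclass
class StudyData:
    """A complete synthetic study, shaped like the real inputs."""

    config: ScenarioConfig
    peak_tables: dict[str, pd.DataFrame]  # sample_id -> mz/intensity/snr
    chemistry: pd.DataFrame  # samples x variables
    genera: pd.DataFrame  # genera x samples, relative abundance (%)
    truth: GroundTruth

    def manifest(self) -> dict:
        return {
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "samples": list(self.peak_tables),
            "peaks_per_sample": {k: len(v) for k, v in self.peak_tables.items()},
        }


def _neutral_window(cfg: ScenarioConfig) -> tuple[float, float]:
    """Neutral-mass window whose [M-H]- ions land inside the m/z window."""
    return (cfg.mass_window[0] + MASS_PROTON, cfg.mass_window[1])


def _build_pools(cfg: ScenarioConfig, rng: np.random.Generator) -> dict[tuple[str, str], np.ndarray]:
    """Distinct-formula pools stratified by (class, group), shared study-wide."""
    window = _neutral_window(cfg)
    pools: dict[tuple[str, str], np.ndarray] = {}
    for ci, cls in enumerate(SEVEN_CLASSES):
        for gi, grp in enumerate(ElementGroup):
            peak_quota = max(
                cfg.class_probs(k)[ci] * cfg.group_probs(k)[gi] * cfg.formulas_per_sample
                for k in range(len(cfg.conditions))
            )
            size = max(8, math.ceil(cfg.pool_factor * peak_quota))
            pools[(cls.value, grp.value)] = sample_formulas_in_class(
                cls, size, rng, window, grp, unique=True
            )
    return pools


def _replicate_formulas(
    cond_index: int,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    pools: dict[tuple[str, str], np.ndarray],
) -> pd.DataFrame:
    """Draw one replicate's formula inventory from the study pools."""
    n_class = rng.multinomial(cfg.formulas_per_sample, cfg.class_probs(cond_index))
    blocks = []
    for ci, cls in enumerate(SEVEN_CLASSES):
        if n_class[ci] == 0:
            continue
        n_group = rng.multinomial(n_class[ci], cfg.group_probs(cond_index))
        for gi, grp in enumerate(ElementGroup):
            want = int(n_group[gi])
            if want == 0:
                continue
            pool = pools[(cls.value, grp.value)]
            take = min(want, len(pool))
            idx = rng.choice(len(pool), size=take, replace=False)
            rows = pool[idx]
            blocks.append(
                pd.DataFrame(
                    {
                        "C": rows[:, 0],
                        "H": rows[:, 1],
                        "O": rows[:, 2],
                        "N": rows[:, 3],
                        "S": rows[:, 4],
                        "compound_class": cls.value,
                        "element_group": grp.value,
                    }
                )
            )
    return pd.concat(blocks, ignore_index=True)


def _noise_mzs(
    count: int,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    exclusion_ppm: float = 2.0,
    max_rounds: int = 200,
) -> np.ndarray:
    """Uniform m/z values with no valid formula within ``exclusion_ppm``.

    Guarantees the noise peaks are truly unassignable at any tolerance up
    to the exclusion radius, so assignment specificity has unambiguous
    ground truth.
    """
    check = AssignmentParams(
        tol_ppm=exclusion_ppm, mz_min=cfg.mass_window[0], mz_max=cfg.mass_window[1]
    )
    out: list[float] = []
    for _ in range(max_rounds):
        if len(out) >= count:
            break
        for mz in rng.uniform(cfg.mass_window[0], cfg.mass_window[1], size=max(2 * (count - len(out)), 8)):
            if len(out) >= count:
                break
            if not enumerate_candidates(mz + MASS_PROTON, check):
                out.append(float(mz))
    if len(out) < count:
        raise InfeasibleScenarioError("could not place unassignable noise peaks")
    return np.array(out[:count])


def generate_sample(
    cond_index: int,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    pools: dict[tuple[str, str], np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One replicate: a shuffled peak list plus its ground-truth table.

    The peak list holds [M-H]- m/z values perturbed by Gaussian ppm
    error, log-normal intensities, S/N mostly above threshold with a
    configured sub-threshold fraction, and unassignable noise peaks.
    """
    if pools is None:
        pools = _build_pools(cfg, rng)
    truth = _replicate_formulas(cond_index, cfg, rng, pools)
    masses = (
        truth["C"].to_numpy() * MASS_C
        + truth["H"].to_numpy() * MASS_H
        + truth["O"].to_numpy() * MASS_O
        + truth["N"].to_numpy() * MASS_N
        + truth["S"].to_numpy() * MASS_S
    )
    mz_exact = np.array([mz_from_neutral_mass(m) for m in masses])
    mz_obs = mz_exact * (1.0 + rng.normal(0.0, cfg.mass_error_ppm_sd, len(mz_exact)) * 1e-6)
    truth = truth.assign(mz_exact=mz_exact, mz_observed=mz_obs)

    n_signal = len(truth)
    intensity = rng.lognormal(mean=13.0, sigma=1.0, size=n_signal)
    low = rng.random(n_signal) < cfg.snr_below_frac
    snr = np.where(low, rng.uniform(1.0, 3.99, n_signal), rng.uniform(4.5, 60.0, n_signal))
    peaks = pd.DataFrame({"mz": mz_obs, "intensity": intensity, "snr": snr})

    n_noise = int(round(cfg.noise_fraction * n_signal))
    if n_noise:
        noise = pd.DataFrame(
            {
                "mz": _noise_mzs(n_noise, cfg, rng),
                "intensity": rng.lognormal(mean=11.5, sigma=0.8, size=n_noise),
                "snr": rng.uniform(4.5, 25.0, n_noise),
            }
        )
        peaks = pd.concat([peaks, noise], ignore_index=True)
    peaks = peaks.iloc[rng.permutation(len(peaks))].reset_index(drop=True)
    return peaks, truth


def pearson_for_spearman(rho_s: float) -> float:
    """Gaussian-copula Pearson parameter giving target Spearman rho.

    For a bivariate Gaussian copula, rho_s = (6/pi) arcsin(r/2); invert.
    """
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def simulate_coupled_pair(
    rho_s: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two vectors whose population Spearman correlation is exactly ``rho_s``."""
    r = pearson_for_spearman(rho_s)
    z1 = rng.normal(size=n)
    z2 = r * z1 + math.sqrt(1.0 - r * r) * rng.normal(size=n)
    return z1, z2


def _normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 0.5) / len(x))


def _genus_table(
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Genus x sample relative abundances with planted copula couplings.

    Coupled genera track the normal scores of their target feature with
    the copula correlation needed for the requested true Spearman rho;
    structural absences zero a genus out in the configured conditions
    (truncating the coupling there, as real detection limits would).
    """
    samples = cfg.sample_ids()
    n = len(samples)
    cond_of = np.repeat(np.arange(len(cfg.conditions)), cfg.replicates)
    names = [c.genus for c in cfg.couplings]
    names += ["Nocardioides"] if "Nocardioides" not in names else []
    names += [g for g in cfg.absences if g not in names]
    names += [f"Genus_{i:02d}" for i in range(1, cfg.n_filler_genera + 1)]
    # canonical draw order: outputs must not depend on config dict order
    names = sorted(dict.fromkeys(names))
    raw = pd.DataFrame(index=names, columns=samples, dtype=float)
    coupled = {c.genus: c for c in cfg.couplings}
    for genus in names:
        if genus in coupled:
            cpl = coupled[genus]
            if cpl.feature not in features.columns:
                raise ValueError(f"coupling target {cpl.feature!r} not among features")
            z_feat = _normal_scores(features[cpl.feature].to_numpy(float))
            r = pearson_for_spearman(cpl.spearman)
            z = r * z_feat + math.sqrt(1.0 - r * r) * rng.normal(size=n)
            base = 2.5
        elif genus == "Nocardioides":
            z = rng.normal(size=n)
            base = 3.5
        else:
            z = rng.normal(size=n)
            base = rng.uniform(0.5, 2.5)
        raw.loc[genus] = np.exp(base + 0.6 * z)
    for genus, gone in cfg.absences.items():
        mask = np.isin(cond_of, gone)
        raw.loc[genus, np.array(samples)[mask]] = 0.0
    return 100.0 * raw / raw.sum(axis=0)


def _chemistry_table(cfg: ScenarioConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    samples = cfg.sample_ids()
    cond_of = np.repeat(np.arange(len(cfg.conditions)), cfg.replicates)
    data = {}
    means = {}
    for var in sorted(cfg.chemistry):  # canonical order: rng draws must not depend on dict order
        mu, sd = cfg.chemistry[var]
        mu = np.asarray(mu, dtype=float)
        data[var] = mu[cond_of] + rng.normal(0.0, sd, len(samples))
        means[var] = mu
    chem = pd.DataFrame(data, index=samples)
    chem["C/N"] = chem["TC"] / chem["TN"]
    mean_df = pd.DataFrame(means, index=list(cfg.conditions))
    mean_df["C/N"] = mean_df["TC"] / mean_df["TN"]
    return chem, mean_df


def _class_group_features(cfg: ScenarioConfig, truth_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-sample class and group percentages straight from the truth."""
    rows = {}
    for sid in cfg.sample_ids():
        t = truth_tables[sid]
        n = len(t)
        row = {}
        cc = t["compound_class"].value_counts()
        gc = t["element_group"].value_counts()
        for cls in SEVEN_CLASSES:
            row[cls.value] = 100.0 * cc.get(cls.value, 0) / n
        for grp in ElementGroup:
            row[grp.value] = 100.0 * gc.get(grp.value, 0) / n
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def generate_study(cfg: ScenarioConfig | None = None) -> StudyData:
    """Generate a full study: peak lists, chemistry, genera, ground truth."""
    if cfg is None:
        cfg = ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)
    pools = _build_pools(cfg, rng)
    peak_tables: dict[str, pd.DataFrame] = {}
    truth_tables: dict[str, pd.DataFrame] = {}
    noise_counts: dict[str, int] = {}
    for k, cond in enumerate(cfg.conditions):
        for r in range(cfg.replicates):
            sid = f"{cond}_r{r + 1}"
            peaks, truth = generate_sample(k, cfg, rng, pools)
            peak_tables[sid] = peaks
            truth_tables[sid] = truth
            noise_counts[sid] = len(peaks) - len(truth)
    chem, chem_means = _chemistry_table(cfg, rng)
    features = pd.concat([_class_group_features(cfg, truth_tables), chem], axis=1)
    genera = _genus_table(cfg, rng, features)
    truth = GroundTruth(truth_tables, chem_means, cfg.couplings, noise_counts)
    return StudyData(cfg, peak_tables, chem, genera, truth)


def study_feature_matrix(
    study: StudyData,
    compositions: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Assemble the network-stage feature matrix and its category map.

    Class/group percentage features come from ``compositions`` (a tidy
    composition table as produced by the pipeline) when given, otherwise
    from the generator's ground truth; chemistry and genus features come
    from the study tables.  Genus features are restricted to the named
    (non-filler) panel.
    """
    cfg = study.config
    if compositions is not None:
        wide = compositions.pivot_table(index="sample_id", columns="name", values="pct")
        cols = [c.value for c in SEVEN_CLASSES] + [g.value for g in ElementGroup]
        cls_grp = wide.reindex(index=cfg.sample_ids(), columns=cols)
    else:
        cls_grp = _class_group_features(cfg, study.truth.formula_tables)
    named = [g for g in study.genera.index if not g.startswith(("Genus_", "Filler_"))]
    genus_feats = study.genera.loc[named].T.loc[cfg.sample_ids()]
    matrix = pd.concat([cls_grp, study.chemistry.loc[cfg.sample_ids()], genus_feats], axis=1)
    categories: dict[str, str] = {}
    for cls in SEVEN_CLASSES:
        categories[cls.value] = "compound_class"
    for grp in ElementGroup:
        categories[grp.value] = "element_group"
    for var in study.chemistry.columns:
        categories[var] = "chemistry"
    for g in named:
        categories[g] = "genus"
    return matrix, categories
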