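"""Synthetic plasma 1H NMR cohort generator with known ground truth.

Simulates 700 MHz CPMG-style frequency-domain plasma spectra: each
metabolite is a set of Lorentzian multiplets (resonance templates carrying
chemical shift, multiplicity, J coupling, amplitude and linewidth), to
which a smooth low-order baseline and i.i.d. Gaussian noise are added.
Case/control cohorts plant known metabolite fold-changes, with lognormal
within-group biological variation and optional inflated-profile outliers.

Fold-changes are planted in *expected constant-sum-normalized intensity*
space, the space in which case:control fold-changes are conventionally
reported for CS-normalized datasets (or, alternatively, in
isoleucine-normalized space).  Because diagnostic windows mix
contributions from overlapping resonances and the constant sum couples
every spectral region to every other, the generator solves a linear
system for the raw case-group concentration multipliers such that the
expected normalized ratio of each planted metabolite's diagnostic window
equals its requested fold-change exactly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
import numpy as np

from .preprocess import DEFAULT_EXCLUDED_REGIONS, DEFAULT_MODEL2_INTERVALS

logger = logging.getLogger(__name__)

#: Spectrometer frequency used for Hz <-> ppm conversion.
SPECTROMETER_MHZ = 700.0

#: Closed multiplicity vocabulary.
MULTIPLICITIES = frozenset({"s", "d", "dd", "t", "q", "m", "broad"})

#: Simulated spectral window (ppm) and grid spacing.
DEFAULT_WINDOW = (0.5, 9.0)
DEFAULT_SPACING = 1.0e-3

#: Default smooth-baseline level (intensity units): emulates the residual
#: macromolecule background of CPMG plasma profiles.
DEFAULT_BASELINE = 12.0

#: Outlier profiles inflate all metabolite multipliers by this factor.
OUTLIER_INFLATION = 5.0


class LibraryParseError(ValueError):
    """A resonance library row could not be parsed."""


@dataclass(frozen=True)
class ResonanceTemplate:
    """One resonance: chemical shift, multiplicity and lineshape parameters.

    ``relative_amplitude`` is the height of the tallest multiplet component
    at unit concentration; ``linewidth`` is the Lorentzian FWHM in ppm.
    """

    metabolite_name: str
    delta: float
    multiplicity: str
    j_coupling: float | None = None
    relative_amplitude: float = 1.0
    linewidth: float = 0.002

    def __post_init__(self):
        if self.multiplicity not in MULTIPLICITIES:
            raise ValueError(
                f"unknown multiplicity {self.multiplicity!r}; "
                f"expected one of {sorted(MULTIPLICITIES)}"
            )
        if self.multiplicity in ("d", "dd", "t", "q") and not self.j_coupling:
            raise ValueError(
                f"multiplicity {self.multiplicity!r} requires a J coupling (Hz)"
            )
        if not (DEFAULT_WINDOW[0] <= self.delta <= DEFAULT_WINDOW[1]):
            raise ValueError(
                f"chemical shift {self.delta} outside the simulated window "
                f"{DEFAULT_WINDOW}"
            )
        if self.relative_amplitude < 0:
            raise ValueError("relative_amplitude must be >= 0")
        if not self.linewidth > 0:
            raise ValueError("linewidth must be > 0")

    def lines(self, freq_mhz: float = SPECTROMETER_MHZ):
        """(ppm offset, height weight) pairs of the multiplet components.

        d -> two equal lines split by J; t -> 1:2:1; q -> 1:3:3:1;
        dd -> four equal lines (second splitting J/2 unless given);
        s/m/broad -> a single line.  Weights are scaled so the tallest
        component has weight 1.
        """
        m = self.multiplicity
        if m in ("s", "m", "broad"):
            return [(0.0, 1.0)]
        j = self.j_coupling / freq_mhz  # ppm
        if m == "d":
            return [(-j / 2, 1.0), (j / 2, 1.0)]
        if m == "t":
            return [(-j, 0.5), (0.0, 1.0), (j, 0.5)]
        if m == "q":
            return [(-1.5 * j, 1 / 3), (-0.5 * j, 1.0), (0.5 * j, 1.0), (1.5 * j, 1 / 3)]
        # dd: splittings J and J/2
        j2 = j / 2
        return [
            (-(j + j2) / 2, 1.0),
            (-(j - j2) / 2, 1.0),
            ((j - j2) / 2, 1.0),
            ((j + j2) / 2, 1.0),
        ]


@dataclass
class SyntheticSpectrum:
    """One simulated (ppm, intensity) profile with sample metadata."""

    ppm_axis: np.ndarray
    intensity: np.ndarray
    sample_id: str
    group: str = ""
    age: float = float("nan")
    gender: str = ""


@dataclass
class GroundTruth:
    """Planted truth for a simulated cohort.

    ``scale_factors[sample_id][metabolite]`` is the per-sample concentration
    multiplier actually drawn; ``group_means`` holds the calibrated
    case-group mean multipliers that realize the planted ``fold_changes``
    in expected CS-normalized bucket space (control means are 1).
    """

    scale_factors: "pd.DataFrame"
    fold_changes: dict[str, float]
    group_means: dict[str, float]


@dataclass
class CohortSpec:
    """Study-design parameters for one simulated case/control cohort."""

    n_control: int = 28
    n_case: int = 10
    fold_changes: dict[str, float] = field(default_factory=dict)
    within_group_cv: float = 0.15
    noise_sd: float = 0.5
    baseline_amplitude: float = DEFAULT_BASELINE
    seed: int = 0
    age_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"HC": (18.0, 54.0), "GM1T2": (3.0, 20.0)}
    )
    gender_proportions: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.25, "GM1T2": 0.40}  # fraction male
    )
    n_outliers: int = 0
    #: space in which ``fold_changes`` are planted: "cs" (expected
    #: constant-sum-normalized bucket ratios) or "ile"
    #: (reference-normalized bucket ratios, Ile reference fixed at 1)
    basis: str = "cs"

    def __post_init__(self):
        if self.basis not in ("cs", "ile"):
            raise ValueError("basis must be 'cs' or 'ile'")
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least 2 samples per group")
        for name, fc in self.fold_changes.items():
            if not fc > 0:
                raise ValueError(f"fold change for {name!r} must be > 0")
        if self.within_group_cv < 0 or self.noise_sd < 0 or self.baseline_amplitude < 0:
            raise ValueError("cv, noise_sd and baseline_amplitude must be >= 0")
        if self.n_outliers < 0 or self.n_outliers > self.n_case:
            raise ValueError("n_outliers must be between 0 and n_case")


# ---------------------------------------------------------------------------
# Resonance library I/O
# ---------------------------------------------------------------------------

_FIELDS = ["metabolite", "delta_ppm", "multiplicity", "j_hz", "rel_amplitude", "linewidth_ppm"]


def load_resonance_library(path) -> list[ResonanceTemplate]:
    """Read a resonance-template CSV (metabolite, delta_ppm, multiplicity, ...)."""
    templates = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                templates.append(
                    ResonanceTemplate(
                        metabolite_name=row["metabolite"].strip(),
                        delta=float(row["delta_ppm"]),
                        multiplicity=row["multiplicity"].strip(),
                        j_coupling=float(row["j_hz"]) if row.get("j_hz") else None,
                        relative_amplitude=float(row.get("rel_amplitude") or 1.0),
                        linewidth=float(row.get("linewidth_ppm") or 0.002),
                    )
                )
            except (KeyError, TypeError) as exc:
                raise LibraryParseError(f"malformed row at line {lineno}: {exc}") from exc
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    if not templates:
        raise LibraryParseError(f"no templates found in {path}")
    return templates


def save_resonance_library(templates, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FIELDS)
        for t in templates:
            writer.writerow(
                [
                    t.metabolite_name,
                    t.delta,
                    t.multiplicity,
                    "" if t.j_coupling is None else t.j_coupling,
                    t.relative_amplitude,
                    t.linewidth,
                ]
            )


def bundled_library() -> list[ResonanceTemplate]:
    """The packaged plasma resonance library.

    Encodes the assigned plasma resonances of the 700 MHz CPMG profile
    (chemical shift, multiplicity, relative height from the published
    median signal-to-noise values) plus synthetic additions at literature
    shifts for 3-aminoisobutyrate, threonine and glutamate, whose panel
    entries lack a printed resonance row.
    """
    with resources.as_file(
        resources.files("nmrmetab.data") / "plasma_resonances.csv"
    ) as p:
        return load_resonance_library(p)


def make_grid(
    window: tuple[float, float] = DEFAULT_WINDOW, spacing: float = DEFAULT_SPACING
) -> np.ndarray:
    n = int(round((window[1] - window[0]) / spacing))
    return np.linspace(window[0], window[1], n + 1)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _render_templates(templates, grid: np.ndarray) -> np.ndarray:
    """Sum of Lorentzian multiplets for a list of templates at unit level."""
    out = np.zeros_like(grid)
    for t in templates:
        gamma = t.linewidth / 2.0  # HWHM
        for offset, weight in t.lines():
            x0 = t.delta + offset
            out += (
                t.relative_amplitude
                * weight
                * gamma**2
                / (gamma**2 + (grid - x0) ** 2)
            )
    return out


def unit_spectra(templates, grid: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Per-metabolite unit spectra: names and a (n_metab, n_points) matrix."""
    by_name: dict[str, list[ResonanceTemplate]] = {}
    for t in templates:
        by_name.setdefault(t.metabolite_name, []).append(t)
    names = list(by_name)
    U = np.empty((len(names), grid.size))
    for i, name in enumerate(names):
        U[i] = _render_templates(by_name[name], grid)
    return names, U


def _baseline(grid: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order (quadratic) baseline with mean level ``amplitude``."""
    if amplitude == 0:
        return np.zeros_like(grid)
    x = (grid - grid[0]) / (grid[-1] - grid[0])
    c0 = rng.uniform(0.8, 1.2)
    c1, c2 = rng.uniform(-0.2, 0.2, size=2)
    return amplitude * (c0 + c1 * x + c2 * x**2)


def render_spectrum(
    levels: dict[str, float],
    templates,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    baseline_amplitude: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_id: str = "S0",
    group: str = "",
) -> SyntheticSpectrum:
    """Render one spectrum from metabolite concentration multipliers.

    Every metabolite in ``levels`` must have at least one template; the
    integrated multiplet area is proportional to
    ``multiplier * relative_amplitude``.
    """
    if grid is None:
        grid = make_grid()
    if rng is None:
        rng = np.random.default_rng(0)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("ppm grid must be strictly increasing")
    names, U = unit_spectra(templates, grid)
    index = {n: i for i, n in enumerate(names)}
    y = np.zeros_like(grid)
    for name, level in levels.items():
        if name not in index:
            raise KeyError(f"metabolite {name!r} absent from the template library")
        y += level * U[index[name]]
    y += _baseline(grid, baseline_amplitude, rng)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=grid.size)
    return SyntheticSpectrum(
        ppm_axis=grid, intensity=y, sample_id=sample_id, group=group
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


class CohortSimulator:
    """Reusable cohort generator: renders unit spectra once, then simulates.

    ``diagnostic_intervals`` maps metabolite -> the fixed (lo, hi) ppm
    window defining its measured targeted intensity (the panel defaults);
    ``excluded_regions`` must match the downstream pipeline's exclusions so
    that the constant-sum calibration and the measurement agree.
    """

    def __init__(
        self,
        templates=None,
        grid: np.ndarray | None = None,
        diagnostic_intervals: dict[str, tuple[float, float]] | None = None,
        excluded_regions=None,
    ):
        self.templates = bundled_library() if templates is None else list(templates)
        self.grid = make_grid() if grid is None else np.asarray(grid, dtype=float)
        self.diagnostic_intervals = (
            dict(DEFAULT_MODEL2_INTERVALS)
            if diagnostic_intervals is None
            else dict(diagnostic_intervals)
        )
        self.excluded_regions = (
            list(DEFAULT_EXCLUDED_REGIONS) if excluded_regions is None else list(excluded_regions)
        )
        self.metabolites, self._U = unit_spectra(self.templates, self.grid)
        self._index = {n: i for i, n in enumerate(self.metabolites)}
        # per-metabolite integrals over the diagnostic windows and over the
        # active (non-excluded) region
        self._window_names = list(self.diagnostic_intervals)
        self._C = np.empty((len(self.metabolites), len(self._window_names)))
        self._widths = np.empty(len(self._window_names))
        for j, name in enumerate(self._window_names):
            lo, hi = sorted(self.diagnostic_intervals[name])
            mask = (self.grid >= lo) & (self.grid <= hi)
            self._C[:, j] = np.trapezoid(self._U[:, mask], self.grid[mask], axis=1)
            self._widths[j] = hi - lo
        active = np.ones(self.grid.size, dtype=bool)
        for r in self.excluded_regions:
            r_lo, r_hi = min(r), max(r)
            active &= ~((self.grid >= r_lo) & (self.grid <= r_hi))
        self._totals = np.array(
            [np.trapezoid(np.where(active, u, 0.0), self.grid) for u in self._U]
        )
        self._active_width = float(np.trapezoid(active.astype(float), self.grid))

    # -- calibration -------------------------------------------------------

    def _window_of(self, name: str) -> int:
        if name not in self.diagnostic_intervals:
            raise KeyError(f"no diagnostic window configured for {name!r}")
        return self._window_names.index(name)

    def calibrate(
        self,
        fold_changes: dict[str, float],
        baseline_amplitude: float = DEFAULT_BASELINE,
        basis: str = "cs",
        reference: str = "Isoleucine",
    ) -> dict[str, float]:
        """Case-group mean multipliers realizing the planted fold-changes.

        ``basis="cs"``: for every planted metabolite, the expected
        CS-normalized targeted intensity (diagnostic-window integral over
        the active-region total) changes by the requested ratio.
        Background metabolites keep unit multipliers; the re-normalization
        by the case group's changed total spectral mass (the constant-sum
        coupling) enters each constraint exactly, since the total is
        itself linear in the unknown multipliers.

        ``basis="ile"``: fold-changes are in reference-normalized space
        (diagnostic window relative to the reference metabolite's window);
        the reference and background multipliers stay at 1 and the system
        is solved in raw window-ratio space, where the constant sum
        cancels.

        Because the diagnostic windows overlap neighbouring resonances,
        the solved multipliers generally differ from the planted ratios:
        the linear system accounts for spectral contamination and for the
        constant-sum coupling so that the *measured* ratios come out
        right in expectation.
        """
        if basis not in ("cs", "ile"):
            raise ValueError("basis must be 'cs' or 'ile'")
        for name in fold_changes:
            if name not in self._index:
                raise KeyError(f"fold change for unknown metabolite {name!r}")
        if not fold_changes:
            return {}
        if basis == "ile":
            fold_changes = dict(fold_changes)
            ref_fc = fold_changes.pop(reference, 1.0)
            if abs(ref_fc - 1.0) > 1e-9:
                raise ValueError(
                    f"the reference metabolite {reference!r} must have "
                    f"fold-change 1.0 on the {basis!r} basis"
                )
            if not fold_changes:
                out = {name: 1.0 for name in self.metabolites}
                return out

        C = self._C
        b = baseline_amplitude * self._widths
        targets = list(fold_changes)
        t_idx = [self._index[n] for n in targets]
        bg_idx = [i for i in range(len(self.metabolites)) if i not in t_idx]
        windows = [self._window_of(n) for n in targets]
        k = len(targets)
        A = np.zeros((k, k))
        rhs = np.zeros(k)

        if basis == "cs":
            totals = self._totals
            b_total = baseline_amplitude * self._active_width
            t_hc = totals.sum() + b_total
            bg_mass = totals[bg_idx].sum() if bg_idx else 0.0
            for r, (name, j) in enumerate(zip(targets, windows)):
                F = fold_changes[name]
                den = C[:, j].sum() + b[j]  # control window expectation
                rest = den - C[t_idx, j].sum() - b[j]
                # case window = F * den * (case total / control total)
                A[r, :] = C[t_idx, j] - F * den * totals[t_idx] / t_hc
                rhs[r] = F * den * (bg_mass + b_total) / t_hc - rest - b[j]
        else:
            j_ref = self._window_of(reference)
            den = C.sum(axis=0) + b  # control expectation per window
            rest = den - C[t_idx, :].sum(axis=0) - b  # non-target signal
            for r, (name, j) in enumerate(zip(targets, windows)):
                F = fold_changes[name]
                A[r, :] = C[t_idx, j] * den[j_ref] - F * den[j] * C[t_idx, j_ref]
                rhs[r] = F * den[j] * (rest[j_ref] + b[j_ref]) - den[j_ref] * (
                    rest[j] + b[j]
                )
        mu_vec = np.linalg.solve(A, rhs)
        if np.any(mu_vec <= 0):
            raise ValueError(
                "calibration produced non-positive multipliers; planted "
                "fold-changes are infeasible for this template mixture"
            )
        out = {name: 1.0 for name in self.metabolites}
        out.update({name: float(v) for name, v in zip(targets, mu_vec)})
        return out

    # -- simulation --------------------------------------------------------

    def simulate(self, spec: CohortSpec):
        """Simulate a cohort; returns (list of SyntheticSpectrum, GroundTruth)."""
        import pandas as pd

        rng = np.random.default_rng(spec.seed)
        group_means = self.calibrate(
            spec.fold_changes, spec.baseline_amplitude, basis=spec.basis
        )

        n = spec.n_control + spec.n_case
        groups = ["HC"] * spec.n_control + ["GM1T2"] * spec.n_case
        ids = [f"HC{i + 1:02d}" for i in range(spec.n_control)] + [
            f"GM{i + 1:02d}" for i in range(spec.n_case)
        ]

        mean_vec = np.ones((n, len(self.metabolites)))
        for j, name in enumerate(self.metabolites):
            mean_vec[spec.n_control :, j] = group_means.get(name, 1.0)

        cv = spec.within_group_cv
        if cv > 0:
            sigma = np.sqrt(np.log1p(cv**2))
            z = rng.normal(size=mean_vec.shape)
            mult = mean_vec * np.exp(sigma * z - sigma**2 / 2.0)
        else:
            mult = mean_vec.copy()
        for i in range(spec.n_outliers):  # inflate the last case profiles
            mult[n - 1 - i] *= OUTLIER_INFLATION

        Y = mult @ self._U
        for i in range(n):
            Y[i] += _baseline(self.grid, spec.baseline_amplitude, rng)
        if spec.noise_sd > 0:
            Y += rng.normal(0.0, spec.noise_sd, size=Y.shape)

        spectra = []
        for i in range(n):
            g = groups[i]
            lo, hi = spec.age_ranges.get(g, (18.0, 54.0))
            age = float(np.round(rng.uniform(lo, hi), 1))
            gender = "M" if rng.random() < spec.gender_proportions.get(g, 0.5) else "F"
            spectra.append(
                SyntheticSpectrum(
                    ppm_axis=self.grid,
                    intensity=Y[i],
                    sample_id=ids[i],
                    group=g,
                    age=age,
                    gender=gender,
                )
            )
        truth = GroundTruth(
            scale_factors=pd.DataFrame(mult, index=ids, columns=self.metabolites),
            fold_changes=dict(spec.fold_changes),
            group_means=group_means,
        )
        return spectra, truth


def simulate_cohort(spec: CohortSpec, templates=None):
    """Convenience wrapper: one-shot cohort simulation.

    For repeated simulation (replicate studies) construct a
    :class:`CohortSimulator` once and call :meth:`~CohortSimulator.simulate`.
    """
    return CohortSimulator(templates).simulate(spec)
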