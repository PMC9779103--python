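"""Forward simulator of a whole-lysate SEC co-fractionation experiment.

The generator emulates the study conditions of a typical tissue-lysate
run: a few hundred proteins with monomer MWs lognormally distributed
around a 42-kDa median, separated over 22 fractions whose mean MWs are
log-spaced across the 15–700 kDa working range of the column. Planted
complexes (homodimers, heterodimers, higher oligomers) and the remaining
free monomers are the *assemblies*; each assembly elutes as a Gaussian
peak in log10-MW centred at its total MW, truncated and renormalised over
the fraction grid so that abundance is conserved. A protein's per-fraction
emPAI is the multiplicity-weighted sum of its assemblies' contributions,
degraded by multiplicative lognormal noise, with values below a detection
floor dropped.

The emitted :class:`SyntheticTruth` (assembly compositions, MWs,
abundances, and each protein's expected state type) is recorded *before*
noise, so recovery of planted complexes by the dimer and co-fractionation
analyses can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .dimers import DimersReport
from .errors import ValidationError
from .models import Experiment, FractionObservation, FractionTable, ProteinRecord
from .taxonomy import DEFAULT_REL_THRESHOLD, ElutionProfile, StateType, classify_state

#: The 8-point fraction mean-MW grid of a representative co-fractionation
#: profile panel (kDa).
EIGHT_POINT_GRID: tuple[float, ...] = (15.0, 30.0, 48.0, 60.0, 90.0, 130.0, 290.0, 400.0)

Composition = tuple[tuple[str, int], ...]


def default_grid(n_fractions: int = 22, low: float = 15.0, high: float = 700.0) -> tuple[float, ...]:
    """Log-spaced fraction mean MWs (ascending, kDa) over the column range."""
    return tuple(np.geomspace(low, high, n_fractions).tolist())


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated SEC run.

    Parameters
    ----------
    n_proteins : int
        Catalogue size of the simulated lysate.
    mw_median_kda, mw_sigma_log : float
        Lognormal monomer-MW distribution: median 42 kDa (a typical
        proteome average) with natural-log sigma 0.5.
    planted_complexes : tuple of compositions
        Each composition is ((accession, multiplicity), ...); accessions
        are the simulator's own (``SIM0000`` ...).
    grid : tuple of float, optional
        Fraction mean MWs ascending; default 22 log-spaced fractions over
        15–700 kDa.
    elution_sigma : float
        Gaussian elution spread in log10-MW units.
    empai_noise_cv : float
        Coefficient of variation of the multiplicative lognormal emPAI noise.
    free_fraction : float
        Share of each planted-complex member left as free monomer.
    abundance_sigma_log : float
        Natural-log sigma of the lognormal molar abundance of unplanted
        (background) proteins, median 1.
    planted_abundance : float
        Molar abundance of each planted assembly (fixed, so planted
        heterodimers are equimolar by construction).
    min_empai : float
        Detection floor; simulated emPAI below it is not observed.
    seed : int
        Base seed; same config + seed reproduces the experiment bit-identically.
    """

    n_proteins: int = 500
    mw_median_kda: float = 42.0
    mw_sigma_log: float = 0.5
    planted_complexes: tuple[Composition, ...] = ()
    grid: tuple[float, ...] | None = None
    n_fractions: int = 22
    elution_sigma: float = 0.05
    empai_noise_cv: float = 0.10
    free_fraction: float = 0.30
    abundance_sigma_log: float = 1.0
    planted_abundance: float = 1.0
    min_empai: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValidationError("n_proteins must be positive")
        if self.mw_median_kda <= 0 or self.mw_sigma_log < 0:
            raise ValidationError("MW distribution parameters must be positive")
        if not 0 <= self.free_fraction <= 1:
            raise ValidationError("free_fraction must be in [0, 1]")
        if self.elution_sigma < 0 or self.empai_noise_cv < 0 or self.min_empai < 0:
            raise ValidationError("noise parameters must be non-negative")

    def resolved_grid(self) -> tuple[float, ...]:
        grid = self.grid if self.grid is not None else default_grid(self.n_fractions)
        return tuple(sorted(float(g) for g in grid))


def accession(i: int) -> str:
    return f"SIM{i:04d}"


@dataclass(frozen=True)
class Assembly:
    """One eluting species: composition, total MW, molar abundance."""

    composition: Composition
    mw_kda: float
    abundance: float


@dataclass
class SyntheticTruth:
    """Ground truth emitted before noise is applied."""

    assemblies: list[Assembly]
    expected_states: dict[str, StateType | None] = field(default_factory=dict)

    def planted_dimer_pairs(self) -> set[tuple[str, str]]:
        """Planted binary complexes as sorted accession pairs.

        Heterodimers ((a,1),(b,1)) yield (a, b); homodimers ((a,2),)
        yield (a, a). Larger assemblies and free monomers are excluded.
        """
        pairs: set[tuple[str, str]] = set()
        for asm in self.assemblies:
            subunits = sorted(
                acc for acc, mult in asm.composition for _ in range(mult)
            )
            if len(subunits) == 2:
                pairs.add((subunits[0], subunits[1]))
        return pairs


def _kernel_weights(mw: float, log_grid: np.ndarray, sigma: float) -> np.ndarray:
    """Normalised Gaussian elution weights over the grid (delta when sigma=0)."""
    if sigma == 0:
        w = np.zeros_like(log_grid)
        w[int(np.argmin(np.abs(log_grid - math.log10(mw))))] = 1.0
        return w
    z = (log_grid - math.log10(mw)) / sigma
    w = np.exp(-0.5 * z * z)
    total = w.sum()
    if total == 0:  # far off-grid with a narrow kernel: collapse to nearest
        w[int(np.argmin(np.abs(log_grid - math.log10(mw))))] = 1.0
        return w
    return w / total


def simulate_lysate(
    config: SimConfig, seed: int | None = None
) -> tuple[SyntheticTruth, Experiment]:
    """Draw a synthetic SEC experiment and its ground truth.

    Fully reproducible: the same config and seed give a bit-identical
    experiment. ``seed`` overrides ``config.seed`` when given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_proteins
    accs = [accession(i) for i in range(n)]
    known = set(accs)
    mws = config.mw_median_kda * np.exp(
        config.mw_sigma_log * rng.standard_normal(n)
    )
    mw_of = dict(zip(accs, mws.tolist()))
    background = np.exp(config.abundance_sigma_log * rng.standard_normal(n))

    complexed: set[str] = set()
    assemblies: list[Assembly] = []
    free_extra: dict[str, float] = {}
    for comp in config.planted_complexes:
        comp = tuple((acc, int(mult)) for acc, mult in comp)
        for acc, mult in comp:
            if acc not in known:
                raise ValidationError(f"planted complex references unknown protein {acc}")
            if mult < 1:
                raise ValidationError(f"multiplicity must be >= 1 for {acc}")
            complexed.add(acc)
        asm_mw = sum(mw_of[acc] * mult for acc, mult in comp)
        bound = config.planted_abundance * (1.0 - config.free_fraction)
        if bound > 0:
            assemblies.append(Assembly(comp, asm_mw, bound))
        for acc, mult in comp:
            free = config.planted_abundance * config.free_fraction * mult
            if free > 0:
                free_extra[acc] = free_extra.get(acc, 0.0) + free

    for i, acc in enumerate(accs):
        ab = free_extra.get(acc, 0.0)
        if acc not in complexed:
            ab += float(background[i])
        if ab > 0:
            assemblies.append(Assembly(((acc, 1),), mw_of[acc], ab))

    grid = np.asarray(config.resolved_grid())
    log_grid = np.log10(grid)
    acc_index = {a: i for i, a in enumerate(accs)}
    signal = np.zeros((n, grid.size))
    for asm in assemblies:
        w = _kernel_weights(asm.mw_kda, log_grid, config.elution_sigma)
        for acc, mult in asm.composition:
            signal[acc_index[acc]] += mult * asm.abundance * w

    if config.empai_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.empai_noise_cv**2))
        noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=signal.shape))
        empai = signal * noise
    else:
        empai = signal.copy()
    empai[empai < config.min_empai] = 0.0

    fractions = []
    for j in range(grid.size - 1, -1, -1):  # elution order: descending MW
        obs = tuple(
            FractionObservation(accs[i], float(empai[i, j]))
            for i in range(n)
            if empai[i, j] > 0
        )
        fractions.append(
            FractionTable(f"F{grid.size - j:02d}", float(grid[j]), obs)
        )
    proteins = {
        acc: ProteinRecord(acc, mw_of[acc], name=f"simulated protein {i}")
        for i, acc in enumerate(accs)
    }
    experiment = Experiment(proteins=proteins, fractions=fractions)

    # expected state type from the noiseless, detection-floored signal
    clean = signal.copy()
    clean[clean < config.min_empai] = 0.0
    expected: dict[str, StateType | None] = {}
    for i, acc in enumerate(accs):
        profile = ElutionProfile(acc, tuple(grid.tolist()), tuple(clean[i].tolist()))
        expected[acc] = classify_state(
            profile, mw_of[acc], DEFAULT_REL_THRESHOLD
        ).state_type

    return SyntheticTruth(assemblies=assemblies, expected_states=expected), experiment


def random_planted_dimers(
    n_dimers: int, n_proteins: int, seed: int = 0
) -> tuple[Composition, ...]:
    """Disjoint random equimolar heterodimer compositions over the catalogue."""
    if 2 * n_dimers > n_proteins:
        raise ValidationError(
            f"cannot plant {n_dimers} disjoint heterodimers among {n_proteins} proteins"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_proteins, size=2 * n_dimers, replace=False)
    return tuple(
        ((accession(int(idx[2 * k])), 1), (accession(int(idx[2 * k + 1])), 1))
        for k in range(n_dimers)
    )


@dataclass(frozen=True)
class RecoveryScore:
    """Recall/precision of planted binary complexes in a dimer report."""

    n_planted: int
    n_reported: int
    recall: float | None     # None when nothing was planted
    precision: float | None  # None when list #2 is empty


def score_recovery(truth: SyntheticTruth, report: DimersReport) -> RecoveryScore:
    """Score a dimer report against the simulator's planted pairs.

    Recall: planted pairs found in list #2 of any fraction, over planted
    pairs. Precision: planted pairs among all distinct list #2 pairs
    (anything not in the truth counts as false).
    """
    planted = truth.planted_dimer_pairs()
    found = report.list2_pairs()
    recall = len(planted & found) / len(planted) if planted else None
    precision = len(planted & found) / len(found) if found else None
    return RecoveryScore(
        n_planted=len(planted),
        n_reported=len(found),
        recall=recall,
        precision=precision,
    )


def sim_config_from_yaml(path: str | Path) -> SimConfig:
    """Load a SimConfig from a YAML mapping of its field names."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if "planted_complexes" in data:
        data["planted_complexes"] = tuple(
            tuple((str(acc), int(mult)) for acc, mult in comp)
            for comp in data["planted_complexes"]
        )
    if data.get("grid") is not None:
        data["grid"] = tuple(float(g) for g in data["grid"])
    return SimConfig(**data)


def write_simulation(
    outdir: str | Path, truth: SyntheticTruth, experiment: Experiment
) -> Path:
    """Write manifest, per-fraction TSVs and the truth table; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["fraction_id\tpath\tmean_mw_kda"]
    for frac in experiment.fractions:
        fname = f"{frac.fraction_id}.tsv"
        cio.write_fraction_table(frac, experiment.proteins, outdir / fname)
        lines.append(f"{frac.fraction_id}\t{fname}\t{frac.mean_mw_kda!r}")
    manifest = outdir / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n", encoding="utf-8")

    truth_lines = ["assembly_id\tcomposition\tmw_kda\tabundance"]
    for k, asm in enumerate(truth.assemblies):
        comp = ";".join(f"{acc}:{mult}" for acc, mult in asm.composition)
        truth_lines.append(f"A{k:05d}\t{comp}\t{asm.mw_kda!r}\t{asm.abundance!r}")
    (outdir / "truth.tsv").write_text("\n".join(truth_lines) + "\n", encoding="utf-8")
    return manifest


def noise_sweep_recall(
    base: SimConfig,
    cvs: list[float],
    seeds: list[int],
    n_dimers: int = 10,
) -> dict[float, float]:
    """Mean planted-dimer recall as a function of emPAI noise level."""
    from .dimers import run_dimers

    out: dict[float, float] = {}
    for cv in cvs:
        recalls = []
        for s in seeds:
            cfg = replace(
                base,
                empai_noise_cv=cv,
                planted_complexes=random_planted_dimers(n_dimers, base.n_proteins, seed=s),
                seed=s,
            )
            truth, exp = simulate_lysate(cfg)
            recalls.append(score_recovery(truth, run_dimers(exp)).recall or 0.0)
        out[cv] = float(np.mean(recalls))
    return out
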