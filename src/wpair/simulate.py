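"""Two-locus case/control genotype simulation.

Genotypes at two diallelic SNPs are generated by random union of gametes from
a four-haplotype model (AB, Ab, aB, ab with a, b the minor alleles), which
fixes the two minor allele frequencies and the linkage disequilibrium
r^2 = D^2/(p1 q1 p2 q2).  Disease risk given the genotype pair (x1, x2) is
either logit-linear in allele dosages,

    logit P(case) = alpha + beta*x1 + gamma*x2 + i*x1*x2,

or an arbitrary 3 x 3 table of per-genotype log odds ("complex effects", not
representable in the allelic form).  Cases and controls are then drawn
retrospectively: P(g | case) is proportional to penetrance(g)*P(g) and
P(g | control) to (1 - penetrance(g))*P(g).

Scenario presets mirror the benchmark designs: a common-MAF null, common-MAF
main-effect/interaction/complex-effect alternatives, a low-MAF (0.1) scenario
with the loci in LD (r^2 = 0.24 among controls), and a very-low-MAF (0.01)
strong-LD (r^2 = 0.64 among controls) complex-effects scenario in which the
full 2 x 9 table almost never has all categories observed.  Published effect
sizes for the alternatives are figure-only, so the preset coefficients are
synthetic stand-ins chosen to reproduce the qualitative orderings (and, for
the rare-variant preset, the stated control/case MAFs of roughly 0.01/0.03).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import optimize, special

from .tables import N_CATEGORIES

__all__ = [
    "HaplotypeModel",
    "PenetranceModel",
    "Scenario",
    "solve_haplotypes",
    "genotype_distribution",
    "case_control_distributions",
    "calibrate_control_scenario",
    "sample_replicate",
    "empirical_r2",
    "dosage_moments",
    "COMPLEX_EFFECTS_LOG_ODDS",
    "scenario_null_common",
    "scenario_main_effects_common",
    "scenario_interaction_common",
    "scenario_complex_common",
    "scenario_lowmaf_ld",
    "scenario_rare_ld_complex",
]

# Haplotypes in the order (AB, Ab, aB, ab); A/B major, a/b minor.
_HAP_MINOR = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])


@dataclass(frozen=True)
class HaplotypeModel:
    """Four-haplotype frequency model for two diallelic loci.

    ``freqs`` are the frequencies of (AB, Ab, aB, ab); dosages count the
    minor alleles a and b.
    """

    freqs: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float).ravel()
        if f.shape != (4,) or np.any(f < -1e-12) or abs(f.sum() - 1) > 1e-9:
            raise ValueError("freqs must be 4 probabilities summing to 1")
        object.__setattr__(self, "freqs", np.clip(f, 0.0, 1.0))

    @property
    def maf1(self) -> float:
        """Minor allele frequency at locus 1 (allele a)."""
        return float(self.freqs[2] + self.freqs[3])

    @property
    def maf2(self) -> float:
        """Minor allele frequency at locus 2 (allele b)."""
        return float(self.freqs[1] + self.freqs[3])

    @property
    def d(self) -> float:
        """LD coefficient D = f(AB)*f(ab) - f(Ab)*f(aB)."""
        f = self.freqs
        return float(f[0] * f[3] - f[1] * f[2])

    @property
    def r2(self) -> float:
        """Haplotype-level r^2 = D^2 / (p1 q1 p2 q2)."""
        p1, p2 = self.maf1, self.maf2
        denom = p1 * (1 - p1) * p2 * (1 - p2)
        if denom == 0:
            return float("nan")
        return self.d**2 / denom


@dataclass(frozen=True)
class PenetranceModel:
    """Disease risk per genotype combination.

    ``form="logit_linear"``: log odds alpha + beta*x1 + gamma*x2 + i*x1*x2.
    ``form="table"``: explicit 3 x 3 log-odds matrix indexed [x1][x2].
    """

    form: str
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    interaction: float = 0.0
    log_odds: np.ndarray | None = None

    def __post_init__(self):
        if self.form == "table":
            lo = np.asarray(self.log_odds, dtype=float)
            if lo.shape != (3, 3):
                raise ValueError("table form requires a 3x3 log-odds matrix")
            object.__setattr__(self, "log_odds", lo)
        elif self.form != "logit_linear":
            raise ValueError(f"unknown penetrance form {self.form!r}")

    def log_odds_matrix(self) -> np.ndarray:
        """3 x 3 matrix of log odds of disease, indexed by (x1, x2)."""
        if self.form == "table":
            return self.log_odds.copy()
        u = np.arange(3)[:, None]
        v = np.arange(3)[None, :]
        return (
            self.alpha + self.beta * u + self.gamma * v + self.interaction * u * v
        ).astype(float)

    def penetrance(self) -> np.ndarray:
        """Length-9 penetrance vector in canonical table order."""
        return special.expit(self.log_odds_matrix().ravel())

    def is_null(self) -> bool:
        lo = self.log_odds_matrix()
        return bool(np.allclose(lo, lo.flat[0]))

    def shifted(self, delta_alpha: float) -> "PenetranceModel":
        """Same relative risks with the baseline log odds shifted."""
        if self.form == "table":
            return PenetranceModel(form="table", log_odds=self.log_odds + delta_alpha)
        return PenetranceModel(
            form="logit_linear",
            alpha=self.alpha + delta_alpha,
            beta=self.beta,
            gamma=self.gamma,
            interaction=self.interaction,
        )


@dataclass(frozen=True)
class Scenario:
    """A complete simulation design: haplotypes, penetrance, sample sizes."""

    haplotypes: HaplotypeModel
    penetrance: PenetranceModel
    n_cases: int = 500
    n_controls: int = 500
    replicates: int = 1000
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1 or self.replicates < 1:
            raise ValueError("n_cases, n_controls and replicates must be >= 1")

    def with_(self, **kw) -> "Scenario":
        d = dict(
            haplotypes=self.haplotypes,
            penetrance=self.penetrance,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
            replicates=self.replicates,
            seed=self.seed,
            label=self.label,
        )
        d.update(kw)
        return Scenario(**d)

    # -- config persistence -------------------------------------------------

    def to_yaml(self, path) -> None:
        pen = self.penetrance
        if pen.form == "table":
            pen_d = {"form": "table", "log_odds": pen.log_odds.tolist()}
        else:
            pen_d = {
                "form": "logit_linear",
                "alpha": float(pen.alpha),
                "beta": float(pen.beta),
                "gamma": float(pen.gamma),
                "interaction": float(pen.interaction),
            }
        doc = {
            "label": self.label,
            "haplotype_freqs": [float(x) for x in self.haplotypes.freqs],
            "penetrance": pen_d,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "replicates": self.replicates,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        pen_d = doc["penetrance"]
        if pen_d["form"] == "table":
            pen = PenetranceModel(form="table", log_odds=np.asarray(pen_d["log_odds"]))
        else:
            pen = PenetranceModel(
                form="logit_linear",
                alpha=pen_d.get("alpha", 0.0),
                beta=pen_d.get("beta", 0.0),
                gamma=pen_d.get("gamma", 0.0),
                interaction=pen_d.get("interaction", 0.0),
            )
        if "haplotype_freqs" in doc:
            hap = HaplotypeModel(np.asarray(doc["haplotype_freqs"]))
        else:
            h = doc["haplotypes"]
            hap = solve_haplotypes(h["maf1"], h["maf2"], h.get("r2", 0.0))
        return cls(
            haplotypes=hap,
            penetrance=pen,
            n_cases=int(doc.get("n_cases", 500)),
            n_controls=int(doc.get("n_controls", 500)),
            replicates=int(doc.get("replicates", 1000)),
            seed=int(doc.get("seed", 0)),
            label=str(doc.get("label", "")),
        )


# ---------------------------------------------------------------------------
# Haplotype construction


def solve_haplotypes(maf1: float, maf2: float, target_r2: float) -> HaplotypeModel:
    """Haplotype frequencies with given MAFs and LD r^2 (minor alleles coupled).

    The positive root D = +sqrt(r^2 * p1 q1 p2 q2) is used, so the minor
    alleles co-occur on the same haplotype more often than by chance.
    Raises a ValueError naming the feasible r^2 range when the implied D
    pushes any haplotype frequency outside [0, 1].
    """
    for name, p in (("maf1", maf1), ("maf2", maf2)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    if not 0 <= target_r2 < 1 + 1e-12:
        raise ValueError("target_r2 must be in [0, 1]")
    p1, p2 = maf1, maf2
    q1, q2 = 1 - p1, 1 - p2
    d = np.sqrt(target_r2 * p1 * q1 * p2 * q2)
    dmax = min(p1 * q2, q1 * p2)  # keeps f(aB), f(Ab) >= 0
    if d > dmax + 1e-12:
        r2_max = dmax**2 / (p1 * q1 * p2 * q2)
        raise ValueError(
            f"target_r2={target_r2} infeasible for MAFs ({maf1}, {maf2}); "
            f"feasible range is [0, {r2_max:.6g}]"
        )
    freqs = np.array(
        [q1 * q2 + d, q1 * p2 - d, p1 * q2 - d, p1 * p2 + d]  # AB, Ab, aB, ab
    )
    return HaplotypeModel(np.clip(freqs, 0.0, 1.0))


def genotype_distribution(hap: HaplotypeModel) -> np.ndarray:
    """Exact 9-category genotype-pair distribution under random gamete union."""
    probs = np.zeros(N_CATEGORIES)
    f = hap.freqs
    for i in range(4):
        for j in range(4):
            u = _HAP_MINOR[i, 0] + _HAP_MINOR[j, 0]
            v = _HAP_MINOR[i, 1] + _HAP_MINOR[j, 1]
            probs[3 * u + v] += f[i] * f[j]
    return probs


# ---------------------------------------------------------------------------
# Retrospective ascertainment


def dosage_moments(probs9) -> dict:
    """MAFs and dosage r^2 implied by a 9-category genotype distribution."""
    p = np.asarray(probs9, dtype=float)
    u = np.repeat(np.arange(3), 3)
    v = np.tile(np.arange(3), 3)
    eu, ev = p @ u, p @ v
    vu, vv = p @ u**2 - eu**2, p @ v**2 - ev**2
    cov = p @ (u * v) - eu * ev
    r2 = float(cov**2 / (vu * vv)) if vu > 0 and vv > 0 else float("nan")
    return {"maf1": float(eu / 2), "maf2": float(ev / 2), "r2": r2}


def case_control_distributions(genoprobs, pen: PenetranceModel):
    """Genotype distributions among cases and controls.

    P(g | case) is proportional to penetrance(g)*P(g), P(g | control) to
    (1 - penetrance(g))*P(g).  Returns (case_dist, control_dist, info) where
    info reports the population prevalence and the MAFs / dosage r^2 implied
    in each group, so scenarios can be calibrated to stated targets.
    """
    p = np.asarray(genoprobs, dtype=float)
    if p.shape != (N_CATEGORIES,) or abs(p.sum() - 1) > 1e-8:
        raise ValueError("genoprobs must be a length-9 distribution")
    f = pen.penetrance()
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("penetrance must lie strictly inside (0, 1)")
    prevalence = float(f @ p)
    case = f * p / prevalence
    control = (1 - f) * p / (1 - prevalence)
    info = {"prevalence": prevalence}
    for grp, dist in (("case", case), ("control", control)):
        m = dosage_moments(dist)
        info.update({f"{grp}_{k}": val for k, val in m.items()})
    return case, control, info


def calibrate_control_scenario(
    target_maf: float,
    target_r2: float,
    pen: PenetranceModel,
) -> HaplotypeModel:
    """Solve haplotype inputs so the *control* distribution hits stated targets.

    Benchmarks state MAF and LD among controls, but retrospective sampling
    under a non-null penetrance shifts the control distribution away from the
    population haplotype model.  This inverts that map numerically: it finds
    (population MAF, population r^2), equal at both loci, such that the
    analytic control-genotype distribution has minor allele frequency
    ``target_maf`` (each locus) and dosage r^2 ``target_r2``.
    """

    def residual(x):
        maf, r2 = x
        if not (0 < maf < 0.5 and 0 <= r2 < 1):
            return [1e3, 1e3]
        try:
            hap = solve_haplotypes(maf, maf, r2)
        except ValueError:
            return [1e3, 1e3]
        _, control, _ = case_control_distributions(genotype_distribution(hap), pen)
        m = dosage_moments(control)
        return [m["maf1"] - target_maf, m["r2"] - target_r2]

    sol = optimize.root(residual, x0=[target_maf, target_r2], method="hybr")
    if not sol.success or max(abs(np.asarray(residual(sol.x)))) > 1e-9:
        raise RuntimeError(f"control calibration failed: {sol.message}")
    return solve_haplotypes(sol.x[0], sol.x[0], sol.x[1])


# ---------------------------------------------------------------------------
# Sampling


def _category_dosages():
    u = np.repeat(np.arange(3), 3)
    v = np.tile(np.arange(3), 3)
    return u, v


def sample_replicate(scenario: Scenario, replicate_index: int):
    """Draw one replicate of (geno1, geno2, phenotype) vectors.

    Cases are multinomial draws from P(g | case), controls from
    P(g | control); deterministic in (scenario.seed, replicate_index).
    Cases come first in the returned vectors (phenotype 1 then 0).
    """
    case, control, _ = case_control_distributions(
        genotype_distribution(scenario.haplotypes), scenario.penetrance
    )
    rng = np.random.default_rng([int(scenario.seed), int(replicate_index)])
    u, v = _category_dosages()
    n_case_cat = rng.multinomial(scenario.n_cases, case)
    n_ctrl_cat = rng.multinomial(scenario.n_controls, control)
    cats = np.concatenate(
        [np.repeat(np.arange(9), n_case_cat), np.repeat(np.arange(9), n_ctrl_cat)]
    )
    phenotype = np.concatenate(
        [np.ones(scenario.n_cases, dtype=np.int64), np.zeros(scenario.n_controls, dtype=np.int64)]
    )
    return u[cats].astype(np.int64), v[cats].astype(np.int64), phenotype


def empirical_r2(geno1, geno2) -> float:
    """Squared Pearson correlation of two dosage vectors (NaN if monomorphic)."""
    g1 = np.asarray(geno1, dtype=float).ravel()
    g2 = np.asarray(geno2, dtype=float).ravel()
    ok = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[ok], g2[ok]
    if g1.size < 2 or g1.std() == 0 or g2.std() == 0:
        return float("nan")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r**2)


# ---------------------------------------------------------------------------
# Scenario presets (effect sizes are synthetic stand-ins; see module docstring)

_BASELINE = float(special.logit(0.1))  # default disease prevalence 0.1

#: Synthetic stand-in 3x3 log-odds table for the "complex effects" generating
#: model (log odds of disease indexed by dosage pair).  Deliberately not
#: representable as alpha + beta*x1 + gamma*x2 + i*x1*x2; with the rare-variant
#: strong-LD haplotype model below it yields control MAF ~ 0.01 and case MAF
#: ~ 0.03.
COMPLEX_EFFECTS_LOG_ODDS = _BASELINE + np.array(
    [
        [0.0, 0.55, 1.20],
        [0.55, 1.30, 0.65],
        [1.20, 0.65, 1.80],
    ]
)


def scenario_null_common(replicates: int = 5000, seed: int = 0) -> Scenario:
    """Null model, both MAFs 0.4, no LD, 500 cases + 500 controls."""
    return Scenario(
        haplotypes=solve_haplotypes(0.4, 0.4, 0.0),
        penetrance=PenetranceModel(form="logit_linear", alpha=_BASELINE),
        replicates=replicates,
        seed=seed,
        label="null-common",
    )


def scenario_main_effects_common(
    beta: float = 0.3, gamma: float = 0.3, replicates: int = 1000, seed: int = 0
) -> Scenario:
    """Allelic main effects at both loci, MAF 0.4, no LD (stand-in sizes)."""
    return Scenario(
        haplotypes=solve_haplotypes(0.4, 0.4, 0.0),
        penetrance=PenetranceModel(
            form="logit_linear", alpha=_BASELINE, beta=beta, gamma=gamma
        ),
        replicates=replicates,
        seed=seed,
        label="main-effects-common",
    )


def scenario_interaction_common(
    interaction: float = 0.35, replicates: int = 1000, seed: int = 0
) -> Scenario:
    """Pure allelic interaction, MAF 0.4, no LD (stand-in size)."""
    return Scenario(
        haplotypes=solve_haplotypes(0.4, 0.4, 0.0),
        penetrance=PenetranceModel(
            form="logit_linear", alpha=_BASELINE, interaction=interaction
        ),
        replicates=replicates,
        seed=seed,
        label="interaction-common",
    )


def scenario_complex_common(replicates: int = 1000, seed: int = 0) -> Scenario:
    """Complex (non-allelic) per-genotype effects at common MAF 0.4."""
    table = _BASELINE + 0.3 * (COMPLEX_EFFECTS_LOG_ODDS - _BASELINE)
    return Scenario(
        haplotypes=solve_haplotypes(0.4, 0.4, 0.0),
        penetrance=PenetranceModel(form="table", log_odds=table),
        replicates=replicates,
        seed=seed,
        label="complex-common",
    )


def scenario_lowmaf_ld(replicates: int = 1000, seed: int = 0) -> Scenario:
    """Low-MAF loci in LD: control MAF 0.1, control dosage r^2 = 0.24.

    A weak-to-moderate allelic effect model (stand-in coefficients); the
    haplotype inputs are calibrated so the analytic control distribution has
    exactly the stated control MAF and r^2.
    """
    pen = PenetranceModel(
        form="logit_linear", alpha=_BASELINE, beta=0.25, gamma=0.25, interaction=0.25
    )
    hap = calibrate_control_scenario(0.1, 0.24, pen)
    return Scenario(
        haplotypes=hap,
        penetrance=pen,
        replicates=replicates,
        seed=seed,
        label="lowmaf-ld",
    )


def scenario_rare_ld_complex(replicates: int = 1000, seed: int = 0) -> Scenario:
    """Very-low-MAF strong-LD complex effects: control MAF 0.01, r^2 = 0.64.

    Uses the synthetic stand-in complex log-odds table; minor alleles are
    enriched in cases (MAF ~ 0.03) and the rarest genotype combinations are
    essentially never all observed in 500+500 samples, so the full-table
    chi-squared test is almost always undefined.
    """
    pen = PenetranceModel(form="table", log_odds=COMPLEX_EFFECTS_LOG_ODDS)
    hap = calibrate_control_scenario(0.01, 0.64, pen)
    return Scenario(
        haplotypes=hap,
        penetrance=pen,
        replicates=replicates,
        seed=seed,
        label="rare-ld-complex",
    )
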