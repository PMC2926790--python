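"""Generative model for reciprocal-cross allele-specific expression.

Three superimposed effects shape the fraction of expression from each
parental X allele in an F1 female brain:

1. **Cell-sampling at X inactivation.**  When X inactivation occurs, the
   pool of brain progenitors is small (a few tens of cells).  Each cell
   independently inactivates one X; the realised fraction ``f`` of cells
   keeping the *maternal* X active is therefore ``K/N`` with
   ``K ~ Binomial(N, p_pat)``, where ``p_pat`` is the per-cell probability
   of inactivating the paternal X.  A single ``f`` is drawn per individual
   and shared by every X-linked gene — this shared factor is what makes
   X-inactivated genes covary across individuals.
2. **Cis-regulatory (eQTL) bias.**  A strain-specific regulatory variant
   gives the reference-strain allele a relative transcriptional strength
   ``rho`` (the other allele has ``1 - rho``), identical in both reciprocal
   crosses.
3. **Parent-of-origin bias.**  ``p_pat != 0.5`` shifts the mean of ``f``
   away from one half, producing opposite shifts of the reference-allele
   fraction in the two reciprocal crosses.

For a gene with escape level ``lam`` (relative transcription from the
inactive X: 0 = fully silenced, 1 = full escape), per-allele output is
allelic strength x active-cell fraction, with inactive-X copies
contributing a ``lam`` multiple.  The expected maternal fraction is

    m = a_m (f + (1-f) lam) / [a_m (f + (1-f) lam) + a_p ((1-f) + f lam)]

where ``(a_m, a_p)`` orients ``(rho, 1-rho)`` by which strain is the
mother.  Special cases: autosomal genes give ``m = a_m / (a_m + a_p)``
(no X inactivation); an Xist-like gene expressed *from the inactive X*
gives ``m = a_m (1-f) / [a_m (1-f) + a_p f]``.

Measurement error is additive Gaussian on the fraction scale (clipped to
[0, 1]); a Beta option with matching mean and SD is available for users
who prefer bounded multiplicative noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionTable, maternal_is_reference, reference_strain
from .errors import ParameterError

XCI_SIM_CLASSES = ("inactivated", "escaper", "partial", "inactive_x_expressed", "autosomal")

#: Default measurement SD on the fraction scale.  Pyrosequencing duplicate
#: runs agree to a mean absolute difference of 1.90 percentage points; for
#: Gaussian error E|X1 - X2| = 2 sigma / sqrt(pi), giving sigma ~ 0.0168.
DEFAULT_MEASUREMENT_SD = 0.019 * math.sqrt(math.pi) / 2.0

#: Default per-cell probability of inactivating the paternal X.  The
#: observed ~6% excess of maternal-allele expression between reciprocal
#: crosses corresponds to 2 (p_pat - 0.5) = 0.06.
DEFAULT_P_PAT = 0.53

#: Default progenitor pool size at X inactivation (within the plausible
#: 30-150 range for mouse brain).
DEFAULT_N_CELLS = 70


@dataclass(frozen=True)
class GeneParams:
    """Simulation truth for one gene.

    Parameters
    ----------
    xci_class:
        One of ``inactivated``, ``escaper``, ``partial``,
        ``inactive_x_expressed`` (Xist-like), ``autosomal``.
    eqtl_ratio:
        rho, the expected reference-allele fraction attributable to cis
        regulation alone, in (0, 1).
    escape_level:
        lam, relative transcription from the inactive X.  Forced to 0 for
        ``inactivated`` and to 1 for ``escaper``; must lie strictly
        between for ``partial``.  Ignored for autosomal genes.
    position_mb:
        Optional chromosomal position for the annotation table.
    """

    gene_id: str
    xci_class: str
    eqtl_ratio: float = 0.5
    escape_level: float | None = None
    position_mb: float | None = None
    chromosome_label: str | None = None

    def __post_init__(self) -> None:
        if self.xci_class not in XCI_SIM_CLASSES:
            raise ParameterError(f"unknown xci_class {self.xci_class!r} for {self.gene_id}")
        if not 0.0 < self.eqtl_ratio < 1.0:
            raise ParameterError(
                f"eqtl_ratio must be in (0, 1); got {self.eqtl_ratio} for {self.gene_id}"
            )
        lam = self.escape_level
        if self.xci_class == "inactivated":
            lam = 0.0
        elif self.xci_class == "escaper":
            lam = 1.0
        elif self.xci_class == "partial":
            if lam is None or not 0.0 < lam < 1.0:
                raise ParameterError(
                    f"partial escaper {self.gene_id} needs escape_level in (0, 1); got {lam}"
                )
        else:
            lam = 0.0
        object.__setattr__(self, "escape_level", float(lam))

    @property
    def chromosome(self) -> str:
        if self.xci_class != "autosomal":
            return "X"
        return self.chromosome_label or "2"


@dataclass
class SimulationParams:
    """Full specification of a simulated reciprocal-cross experiment.

    ``strain_pair`` names the reference strain first ("PWD-AKR" means the
    PWD allele defines ``ref_fraction``); the two reciprocal cross ids are
    derived from it.  ``litters_per_cross`` splits the females of each
    cross into litters; when ``include_males`` is set, one male sibling
    per litter is added as a pyrosequencing control.
    """

    genes: Sequence[GeneParams]
    n_cells: int = DEFAULT_N_CELLS
    p_pat: float = DEFAULT_P_PAT
    measurement_sd: float = DEFAULT_MEASUREMENT_SD
    n_females_per_cross: int = 18
    n_replicates: int = 2
    strain_pair: str = "PWD-AKR"
    litters_per_cross: tuple[int, int] = (5, 4)
    include_males: bool = True
    noise: str = "gaussian"  # or "beta"
    deterministic_f: bool = False  # N -> infinity limit: f = p_pat exactly

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if not 0.0 <= self.p_pat <= 1.0:
            raise ParameterError("p_pat must be in [0, 1]")
        if self.measurement_sd < 0:
            raise ParameterError("measurement_sd must be >= 0")
        if self.n_females_per_cross < 1:
            raise ParameterError("need at least one female per cross")
        if self.n_replicates < 1:
            raise ParameterError("need at least one replicate")
        if self.noise not in ("gaussian", "beta"):
            raise ParameterError(f"noise must be 'gaussian' or 'beta', got {self.noise!r}")
        if not self.genes:
            raise ParameterError("at least one gene is required")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ParameterError("duplicate gene_id in simulation roster")

    @property
    def crosses(self) -> tuple[str, str]:
        ref, alt = self.strain_pair.split("-")
        return (f"{ref}x{alt}", f"{alt}x{ref}")


def draw_inactivation_fraction(
    params: SimulationParams, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Draw per-individual maternal-active cell fractions f = K/N.

    ``K ~ Binomial(n_cells, p_pat)`` independently per individual, so f
    has mean ``p_pat`` and variance ``p_pat (1 - p_pat) / n_cells``.
    With ``deterministic_f`` set, returns ``p_pat`` exactly (the infinite
    pool limit).
    """
    if params.n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if params.deterministic_f:
        return np.full(size, params.p_pat)
    return rng.binomial(params.n_cells, params.p_pat, size=size) / params.n_cells


def expected_allelic_fraction(
    f: float | np.ndarray, gene: GeneParams, ref_is_maternal: bool
) -> float | np.ndarray:
    """Expected maternal-allele fraction for a gene given f.

    ``f`` is the fraction of cells with the maternal X active.  The
    allelic strengths ``(a_m, a_p)`` are ``(rho, 1-rho)`` when the
    reference strain is the mother and swapped otherwise.
    """
    rho, lam = gene.eqtl_ratio, gene.escape_level
    a_m, a_p = (rho, 1.0 - rho) if ref_is_maternal else (1.0 - rho, rho)
    f = np.asarray(f, dtype=float)
    if gene.xci_class == "autosomal":
        m = np.full_like(f, a_m / (a_m + a_p))
    elif gene.xci_class == "inactive_x_expressed":
        num = a_m * (1.0 - f)
        m = num / (num + a_p * f)
    else:
        num = a_m * (f + (1.0 - f) * lam)
        m = num / (num + a_p * ((1.0 - f) + f * lam))
    return float(m) if m.ndim == 0 else m


def _observe(m: np.ndarray, params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Apply measurement noise to expected fractions."""
    sd = params.measurement_sd
    if sd == 0:
        return m.copy()
    if params.noise == "gaussian":
        return np.clip(m + rng.normal(0.0, sd, size=m.shape), 0.0, 1.0)
    # Beta noise with matching mean and (approximate) SD; degenerate means
    # pass through unchanged.
    out = m.copy()
    interior = (m > 0) & (m < 1)
    mi = m[interior]
    var = np.minimum(sd**2, mi * (1 - mi) * 0.999)
    nu = mi * (1 - mi) / var - 1.0
    out[interior] = rng.beta(mi * nu, (1 - mi) * nu)
    return out


def simulate_dataset(
    params: SimulationParams,
    rng: np.random.Generator | int | None = None,
) -> ExpressionTable:
    """Simulate one reciprocal-cross experiment as an :class:`ExpressionTable`.

    Each female individual receives a single inactivation fraction f shared
    by all X-linked genes; each (gene, individual, replicate) observation
    is the gene's expected maternal fraction (re-expressed as the
    reference-strain fraction) plus measurement noise.  Male siblings, when
    included, carry a single maternal X: their maternal fraction is exactly
    1 for X-linked genes, with the same measurement noise.
    """
    rng = np.random.default_rng(rng)
    cross_a, cross_b = params.crosses
    pair = params.strain_pair
    genes = sorted(params.genes, key=lambda g: g.gene_id)
    n_rep = params.n_replicates

    frames: list[pd.DataFrame] = []
    for cross in (cross_a, cross_b):
        ref_mat = maternal_is_reference(cross, pair)
        n_f = params.n_females_per_cross
        f = draw_inactivation_fraction(params, rng, n_f)
        n_litters = params.litters_per_cross[0 if cross == cross_a else 1]
        ind_ids = [f"{cross}_F{i + 1}" for i in range(n_f)]
        litters = [f"{cross}_L{i % n_litters + 1}" for i in range(n_f)]
        sexes = ["female"] * n_f
        f_all = list(f)
        if params.include_males:
            for j in range(n_litters):
                ind_ids.append(f"{cross}_M{j + 1}")
                litters.append(f"{cross}_L{j + 1}")
                sexes.append("male")
                f_all.append(1.0)  # single maternal X
        n_ind = len(ind_ids)
        f_vec = np.asarray(f_all)
        is_male = np.array([s == "male" for s in sexes])

        # expected maternal fraction, genes x individuals
        m = np.empty((len(genes), n_ind))
        for gi, gene in enumerate(genes):
            m[gi] = expected_allelic_fraction(f_vec, gene, ref_mat)
            if gene.xci_class != "autosomal":
                # a male's X-linked signal is entirely maternal
                m[gi, is_male] = 1.0

        m_rep = np.repeat(m[:, :, None], n_rep, axis=2)
        obs_maternal = _observe(m_rep, params, rng)
        ref_fraction = obs_maternal if ref_mat else 1.0 - obs_maternal

        frames.append(
            pd.DataFrame(
                {
                    "gene_id": np.repeat([g.gene_id for g in genes], n_ind * n_rep),
                    "individual_id": np.tile(np.repeat(ind_ids, n_rep), len(genes)),
                    "cross_id": cross,
                    "strain_pair_id": pair,
                    "litter_id": np.tile(np.repeat(litters, n_rep), len(genes)),
                    "sex": np.tile(np.repeat(sexes, n_rep), len(genes)),
                    "replicate_index": np.tile(
                        np.arange(1, n_rep + 1), len(genes) * n_ind
                    ),
                    "ref_fraction": ref_fraction.ravel(),
                }
            )
        )

    data = pd.concat(frames, ignore_index=True)
    ann = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chromosome": [g.chromosome for g in genes],
            "position_mb": [g.position_mb for g in genes],
            "xci_class_known": [g.xci_class for g in genes],
        }
    )
    return ExpressionTable(data, ann)


# ---------------------------------------------------------------------------
# Default rosters emulating the published reciprocal-cross designs


_PWD_AKR_INACTIVATED = [
    "Ctps2", "Plxna3", "Syn1", "Phf6", "Taf1", "Syap1", "Maoa", "Zfx", "Usp9x",
    "Ddx3x", "Ikbkg", "Prkx", "Nxt2", "Gpm6b", "Nudt11", "Zbtb33", "Sh3bgrl",
    "Fundc1", "Wdr13", "Hcfc1", "Rbmx", "Uba1", "L1cam", "Ofd1", "Crsp2",
    "Cstf2", "Ids", "Tsix", "Xite",
]

_AUTOSOMAL = [
    ("Pex7", "10", 0.50),
    ("NM_023057", "2", 0.52),
    ("Prkar2b", "12", 0.45),
    ("Hibadh", "6", 0.40),
    ("Rgs17", "10", 0.55),
    ("Cab39l", "14", 0.50),
    ("Trpm6", "19", 0.60),
    ("Tmem109", "19", 0.48),
]

_B6_CAST_INACTIVATED = _PWD_AKR_INACTIVATED[:14]


def _inactivated_genes(names: Sequence[str]) -> list[GeneParams]:
    # Deterministic cis-effect spread: reference-allele strengths evenly
    # spaced in [0.35, 0.65] across the inactivated roster.
    rhos = np.linspace(0.35, 0.65, len(names))
    return [
        GeneParams(n, "inactivated", eqtl_ratio=float(r), position_mb=float(5 + 4 * i))
        for i, (n, r) in enumerate(zip(names, rhos))
    ]


def default_params(strain_pair: str = "PWD-AKR") -> SimulationParams:
    """Packaged reciprocal-cross simulation defaults.

    ``"PWD-AKR"``: 41 genes (29 X-inactivated, 2 full escapers, 1 partial
    escaper with 30% inactive-X expression, 1 Xist-like gene expressed from
    the inactive X with a strong cis bias toward the non-reference allele,
    8 autosomal controls), 18 females per reciprocal cross in 5 + 4
    litters, duplicate measurements, one male control per litter.

    ``"B6-CAST"``: the smaller companion design — 18 X-linked genes plus 2
    autosomal controls in 11 + 11 females from 3 + 4 litters.  Here the
    Xist-like gene is biased toward the reference (B6) allele.
    """
    if strain_pair == "PWD-AKR":
        genes = _inactivated_genes(_PWD_AKR_INACTIVATED)
        genes += [
            GeneParams("Eif2s3x", "escaper", eqtl_ratio=0.60, position_mb=94.0),
            GeneParams("Utx", "escaper", eqtl_ratio=0.55, position_mb=18.0),
            GeneParams("Jarid1c", "partial", eqtl_ratio=0.50, escape_level=0.3,
                       position_mb=152.0),
            GeneParams("Xist", "inactive_x_expressed", eqtl_ratio=0.10, position_mb=103.0),
        ]
        genes += [
            GeneParams(n, "autosomal", eqtl_ratio=r, position_mb=50.0, chromosome_label=c)
            for n, c, r in _AUTOSOMAL
        ]
        return SimulationParams(
            genes=genes,
            n_females_per_cross=18,
            litters_per_cross=(5, 4),
            strain_pair="PWD-AKR",
        )
    if strain_pair == "B6-CAST":
        genes = _inactivated_genes(_B6_CAST_INACTIVATED)
        genes += [
            GeneParams("Eif2s3x", "escaper", eqtl_ratio=0.60, position_mb=94.0),
            GeneParams("Utx", "escaper", eqtl_ratio=0.55, position_mb=18.0),
            GeneParams("Jarid1c", "partial", eqtl_ratio=0.50, escape_level=0.3,
                       position_mb=152.0),
            GeneParams("Xist", "inactive_x_expressed", eqtl_ratio=0.80, position_mb=103.0),
            GeneParams("Pex7", "autosomal", eqtl_ratio=0.50, position_mb=50.0,
                       chromosome_label="10"),
            GeneParams("NM_023057", "autosomal", eqtl_ratio=0.52, position_mb=50.0,
                       chromosome_label="2"),
        ]
        return SimulationParams(
            genes=genes,
            n_females_per_cross=11,
            litters_per_cross=(3, 4),
            strain_pair="B6-CAST",
        )
    raise ParameterError(f"no packaged defaults for strain pair {strain_pair!r}")
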