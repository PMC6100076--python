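"""Seeded synthetic descriptor/response generator.

Emulates the statistical structure of a small-molecule efflux-ratio
dataset: seven descriptor roles (total surface area, molecular volume,
polar surface area, H-bond donor count, rotatable-bond count,
aromatic-ring count, nitrogen+oxygen count), optional strongly collinear
companions (a molecular-weight-like column tracking volume, an HBA-like
column tracking nN+O), and a nonlinear response in which log ER rises and
then falls with the HBD count (peak near 6) and with a lipophilicity
proxy (the aromatic-ring count, which stands in for log P).

The response surface is regime-structured: a smooth weight in the
rotatable-bond count shifts the balance between the HBD term and the
lipophilicity term, so flexible and rigid molecules follow different
local structure-activity relationships.  This heterogeneity is what makes
an ensemble of local models plus a meta-regressor the right tool; a
single global regressor must compromise across regimes.

Only the statistical shape matters: the generator makes no attempt to
mimic real drug chemical space.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

__all__ = ["SyntheticSpec", "generate_dataset", "generate_collinear_pair", "GENERATIVE_DESCRIPTORS"]

#: descriptors that carry signal in the default response surface
GENERATIVE_DESCRIPTORS = ("HBD", "nAr", "Vm", "nRot")

DESCRIPTOR_NAMES = ("SA", "Vm", "PSA", "HBD", "nRot", "nAr", "nNO")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic efflux-ratio dataset.

    The response surface combines two inverted-U terms, a linear size
    term, and a regime interaction:

        log ER = a_hbd * cH(nRot) * exp(-(HBD - hbd_peak)^2 / (2 w_hbd^2))
               + a_lip * cL(nRot) * exp(-(nAr - lip_peak)^2 / (2 w_lip^2))
               + a_size * z(Vm) + noise,  noise ~ N(0, noise_sd^2)

    where w(nRot) = sigmoid((nRot - regime_center)/regime_width) and the
    regime coefficients cH = 1/2 + s (w - 1/2), cL = 1/2 + s (1/2 - w)
    with s = ``interaction_strength``: at s = 0 the surface is purely
    additive; at s = 1 the H-bond-donor term dominates for flexible
    molecules (high nRot) and the lipophilicity term for rigid ones.
    Marginally over nRot both binned means still rise to the configured
    peaks and fall beyond them.  Amplitudes are in log-ER (log10) units.
    """

    n_samples: int = 200
    noise_sd: float = 0.1
    seed: int = 0
    hbd_peak: float = 6.0
    hbd_width: float = 2.5
    hbd_amplitude: float = 1.0
    lip_peak: float = 3.0
    lip_width: float = 1.5
    lip_amplitude: float = 0.6
    size_slope: float = 0.3
    interaction_strength: float = 1.0
    regime_center: float = 5.0
    regime_width: float = 1.5
    baseline: float = 0.0
    include_collinear: bool = False
    collinear_r2: float = 0.98

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _descriptor_matrix(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_samples
    # continuous size/polarity descriptors on drug-like scales
    sa = rng.normal(450.0, 90.0, size=n)                      # total surface area, A^2
    vm = 0.75 * sa + rng.normal(0.0, 55.0, size=n)            # molecular volume, mildly size-linked
    psa = np.clip(rng.normal(85.0, 30.0, size=n), 5.0, None)  # polar surface area, A^2
    # integer descriptors: truncated Poisson / uniform mixtures
    hbd = np.where(
        rng.random(n) < 0.8,
        np.minimum(rng.poisson(3.0, size=n), 10),
        rng.integers(0, 11, size=n),
    ).astype(float)
    nrot = np.minimum(rng.poisson(5.0, size=n), 15).astype(float)
    nar = np.where(
        rng.random(n) < 0.8,
        np.minimum(rng.poisson(2.0, size=n), 6),
        rng.integers(0, 7, size=n),
    ).astype(float)
    nno = np.minimum(hbd + rng.poisson(3.0, size=n), 16).astype(float)
    df = pd.DataFrame(
        {
            "SA": sa,
            "Vm": vm,
            "PSA": psa,
            "HBD": hbd,
            "nRot": nrot,
            "nAr": nar,
            "nNO": nno,
        },
        index=[f"mol{i + 1}" for i in range(n)],
    )
    return df


def _response_surface(spec: SyntheticSpec, X: pd.DataFrame) -> np.ndarray:
    hbd = X["HBD"].to_numpy(dtype=float)
    nar = X["nAr"].to_numpy(dtype=float)
    vm = X["Vm"].to_numpy(dtype=float)
    nrot = X["nRot"].to_numpy(dtype=float)
    z_vm = (vm - vm.mean()) / vm.std(ddof=1)
    bump_hbd = spec.hbd_amplitude * np.exp(
        -((hbd - spec.hbd_peak) ** 2) / (2.0 * spec.hbd_width**2)
    )
    bump_lip = spec.lip_amplitude * np.exp(
        -((nar - spec.lip_peak) ** 2) / (2.0 * spec.lip_width**2)
    )
    w = 1.0 / (1.0 + np.exp(-(nrot - spec.regime_center) / spec.regime_width))
    s = spec.interaction_strength
    coef_h = 0.5 + s * (w - 0.5)
    coef_l = 0.5 + s * (0.5 - w)
    return spec.baseline + coef_h * bump_hbd + coef_l * bump_lip + spec.size_slope * z_vm


def generate_dataset(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (molecule table, descriptor table) for one seeded draw.

    The molecule table has columns ``id`` and ``log_er`` (plus ``er``);
    the descriptor table is indexed by the same ids.  With
    ``include_collinear=True`` two redundant columns are appended: ``MW``
    tracking Vm at the configured squared correlation and ``HBA`` tracking
    nNO, for exercising the intercorrelation filter.
    """
    rng = np.random.default_rng(spec.seed)
    X = _descriptor_matrix(spec, rng)
    signal = _response_surface(spec, X)
    log_er = signal + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    if spec.include_collinear:
        X["MW"] = _collinear_companion(X["Vm"].to_numpy(), spec.collinear_r2, rng)
        X["HBA"] = _collinear_companion(X["nNO"].to_numpy(), spec.collinear_r2, rng)
    molecules = pd.DataFrame(
        {"id": X.index, "er": np.power(10.0, log_er), "log_er": log_er}
    ).reset_index(drop=True)
    return molecules, X


def _collinear_companion(
    base: np.ndarray, target_r2: float, rng: np.random.Generator
) -> np.ndarray:
    """A column whose squared correlation with ``base`` targets target_r2.

    With z the standardized base and e independent noise, x = z * sqrt(r2)
    + e * sqrt(1 - r2) has population correlation sqrt(r2) with the base.
    """
    if not 0.0 < target_r2 <= 1.0:
        raise ValueError("target r2 must be in (0, 1]")
    z = (base - base.mean()) / base.std(ddof=1)
    if target_r2 == 1.0:
        return base.copy()
    e = rng.normal(0.0, 1.0, size=base.size)
    return np.sqrt(target_r2) * z + np.sqrt(1.0 - target_r2) * e


def generate_collinear_pair(
    n: int = 1000, target_r2: float = 0.98, seed: int = 0
) -> pd.DataFrame:
    """Standalone pair of columns with a target squared correlation."""
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 1.0, size=n)
    companion = _collinear_companion(base, target_r2, rng)
    return pd.DataFrame(
        {"base": base, "companion": companion},
        index=[f"s{i + 1}" for i in range(n)],
    )
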