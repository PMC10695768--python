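"""Synthetic data generators with known ground truth.

Two generators emulate the statistical structure the analyses are built for,
so every pipeline stage can be exercised without any imaging data:

* ``generate_synapse_table`` builds a per-contact morphology table in which
  contacts of one bouton share a bouton-level lognormal factor.  The key
  knobs are the within-bouton log-SD (sigma_w) and the between-bouton log-SD
  (sigma_b): with sigma_w < sigma_b the contacts of an MSB are more alike
  than contacts scattered across boutons, which is exactly the effect the
  variance comparison is meant to detect.  Bouton volume grows as a power of
  the contact count, mirroring the observation that boutons forming more
  synapses are larger.

* ``generate_neurite_tree`` grows a dendritic arbor whose primary branches
  fan out from the soma inside a cone, so branches diverge and self-proximity
  falls off with distance from the soma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometrics import MEASURES, NeuriteTree, validate_synapse_table
from .network import AZCountDistribution, sample_az_counts

__all__ = [
    "SynapseGenParams",
    "TreeGenParams",
    "generate_synapse_table",
    "generate_neurite_tree",
]


@dataclass(frozen=True)
class SynapseGenParams:
    """Ground-truth parameters for the synthetic synapse-morphology table.

    Log-scale means are set to plausible hippocampal values (median spine
    volume ~0.04 um^3, PSD area ~0.05 um^2, AZ area ~0.06 um^2); synaptic
    size distributions are right-skewed, hence the lognormal family.

    ``between_bouton_log_sd`` (sigma_b) is the total log-SD of a contact
    measure across the population, ``within_bouton_log_sd`` (sigma_w) the
    log-SD among contacts of one bouton; the shared bouton-level factor
    carries the remaining variance sigma_b^2 - sigma_w^2, so the intraclass
    correlation within a bouton is 1 - sigma_w^2/sigma_b^2.  Setting
    sigma_w = sigma_b removes the bouton factor entirely: contacts of an MSB
    are then no more alike than contacts of different boutons, the null case
    of the variance comparison.
    """

    n_boutons: int = 200
    az_dist: AZCountDistribution = field(
        default_factory=AZCountDistribution.default_so)
    log_means: tuple[float, float, float] = (
        float(np.log(0.04)), float(np.log(0.05)), float(np.log(0.06)))
    within_bouton_log_sd: float = 0.35    # sigma_w
    between_bouton_log_sd: float = 0.80   # sigma_b
    bouton_volume_exponent: float = 1.0   # gamma: volume ~ alpha^gamma
    bouton_volume_scale: float = 0.10     # um^3 at alpha = 1
    bouton_volume_log_sd: float = 0.30
    measure_correlation: float = 0.6      # rho_m across the three measures
    n_dendrites: int = 20
    dendrite_length_um: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_bouton_log_sd < 0 or self.between_bouton_log_sd < 0:
            raise ValueError("log-SDs must be non-negative")
        if self.within_bouton_log_sd > self.between_bouton_log_sd:
            raise ValueError(
                "within-bouton log-SD cannot exceed the total between-bouton log-SD")
        if not -1.0 <= self.measure_correlation <= 1.0:
            raise ValueError("measure_correlation must be in [-1, 1]")
        if self.n_boutons < 1 or self.n_dendrites < 1:
            raise ValueError("counts must be positive")


def _equicorrelated(n_rows: int, rho: float, sd: float,
                    rng: np.random.Generator) -> np.ndarray:
    """(n_rows, 3) Gaussians, equicorrelated across columns with rho, SD sd."""
    m = len(MEASURES)
    if rho < -1.0 / (m - 1):
        raise ValueError(f"equicorrelation must be >= {-1.0 / (m - 1):.3f}")
    cov = sd * sd * ((1 - rho) * np.eye(m) + rho * np.ones((m, m)))
    chol = np.linalg.cholesky(cov) if sd > 0 else np.zeros((m, m))
    return rng.standard_normal((n_rows, m)) @ chol.T


def generate_synapse_table(params: SynapseGenParams,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a synapse-morphology table with bouton-level shared factors.

    Bouton i draws a contact count alpha_i and a bouton-level log-factor
    (equicorrelated across the three measures, SD sqrt(sigma_b^2 - sigma_w^2));
    contact j adds an independent residual (SD sigma_w) and exponentiates, so
    contacts across boutons have total log-SD sigma_b.  Bouton volume is
    scale * alpha^gamma times lognormal noise.  Contacts land on random
    dendrites at uniform positions.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    alphas = sample_az_counts(params.n_boutons, params.az_dist, rng)
    shared_sd = float(np.sqrt(params.between_bouton_log_sd ** 2
                              - params.within_bouton_log_sd ** 2))
    b_factor = _equicorrelated(params.n_boutons, params.measure_correlation,
                               shared_sd, rng)
    bouton_vol = (params.bouton_volume_scale
                  * alphas.astype(float) ** params.bouton_volume_exponent
                  * np.exp(params.bouton_volume_log_sd * rng.standard_normal(
                      params.n_boutons)))
    n_contacts = int(alphas.sum())
    eps = _equicorrelated(n_contacts, params.measure_correlation,
                          params.within_bouton_log_sd, rng)
    bouton_of_contact = np.repeat(np.arange(params.n_boutons), alphas)
    mu = np.asarray(params.log_means)
    log_vals = mu[None, :] + b_factor[bouton_of_contact] + eps
    vals = np.exp(log_vals)

    table = pd.DataFrame({
        "contact_id": np.arange(n_contacts),
        "bouton_id": bouton_of_contact,
        "dendrite_id": rng.integers(0, params.n_dendrites, size=n_contacts),
        "position_um": rng.uniform(0, params.dendrite_length_um, size=n_contacts),
        MEASURES[0]: vals[:, 0],
        MEASURES[1]: vals[:, 1],
        MEASURES[2]: vals[:, 2],
        "bouton_volume_um3": bouton_vol[bouton_of_contact],
        "contact_count": alphas[bouton_of_contact],
    })
    return validate_synapse_table(table)


@dataclass(frozen=True)
class TreeGenParams:
    """Growth parameters for the synthetic fanned dendritic arbor.

    Primary branches leave the soma inside a cone of ``fan_half_angle_deg``
    around a common axis and wander with small angular noise; they split with
    probability ``branch_probability`` per micrometre grown.  Nodes are laid
    down every ``node_spacing`` micrometres, so the emitted tree is already at
    constant arc-length spacing.
    """

    n_primary_branches: int = 5
    branch_probability: float = 0.008   # per um
    fan_half_angle_deg: float = 40.0
    total_extent_um: float = 120.0      # path length at which growth stops
    node_spacing: float = 0.5           # um
    wobble_deg: float = 4.0             # direction noise per step
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fan_half_angle_deg <= 90:
            raise ValueError("fan half-angle must be in (0, 90] degrees")
        if self.node_spacing <= 0 or self.total_extent_um <= 0:
            raise ValueError("lengths must be positive")
        if not 0 <= self.branch_probability:
            raise ValueError("branch_probability must be non-negative")


_AXIS = np.array([1.0, 0.0, 0.0])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _sample_in_cone(axis: np.ndarray, half_angle_rad: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniform direction within a cone around ``axis``."""
    cos_max = np.cos(half_angle_rad)
    c = rng.uniform(cos_max, 1.0)
    s = np.sqrt(1 - c * c)
    phi = rng.uniform(0, 2 * np.pi)
    # orthonormal frame around axis
    a = _unit(axis)
    helper = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(a, helper))
    e2 = np.cross(a, e1)
    return c * a + s * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _clamp_to_cone(d: np.ndarray, axis: np.ndarray, half_angle_rad: float) -> np.ndarray:
    """Pull a direction back inside the fan cone if it strayed out."""
    d = _unit(d)
    cos_a = float(d @ axis)
    if cos_a >= np.cos(half_angle_rad):
        return d
    # rotate toward the axis until exactly on the cone boundary
    perp = d - cos_a * axis
    norm = np.linalg.norm(perp)
    if norm < 1e-12:
        return axis.copy()
    perp /= norm
    return np.cos(half_angle_rad) * axis + np.sin(half_angle_rad) * perp


def generate_neurite_tree(params: TreeGenParams,
                          rng: np.random.Generator | None = None) -> NeuriteTree:
    """Grow a fanned dendritic arbor from a soma at the origin."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    xyz = [np.zeros(3)]
    parent = [-1]
    wobble = np.deg2rad(params.wobble_deg)
    half = np.deg2rad(params.fan_half_angle_deg)
    # (parent node index, position, direction, path length grown so far)
    tips = []
    for _ in range(params.n_primary_branches):
        tips.append((0, np.zeros(3), _sample_in_cone(_AXIS, half, rng), 0.0))
    step = params.node_spacing
    while tips:
        pidx, pos, d, grown = tips.pop()
        d = _clamp_to_cone(d + wobble * rng.standard_normal(3), _AXIS, half)
        pos = pos + step * d
        grown += step
        xyz.append(pos)
        parent.append(pidx)
        idx = len(xyz) - 1
        if grown >= params.total_extent_um:
            continue
        if rng.random() < params.branch_probability * step:
            # daughters diverge so the arbor keeps fanning out distally
            for _ in range(2):
                child_d = _clamp_to_cone(
                    d + 0.5 * rng.standard_normal(3), _AXIS, half)
                tips.append((idx, pos, child_d, grown))
        else:
            tips.append((idx, pos, d, grown))
    return NeuriteTree(xyz=np.asarray(xyz), parent=np.asarray(parent, dtype=int))
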