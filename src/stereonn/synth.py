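"""Synthetic fixtures with the statistical and geometric shape of the real task.

Two generators are provided:

* :func:`simulate_feature_table` plants a known nonlinear map from a handful
  of informative features (uniform on [0, 1]) to an S-selectivity percentage,
  adds Gaussian label noise on the S% scale, and returns train / validation-I /
  validation-II splits sized like the experimental campaign (17 / 10 / 3
  ligands) together with the ground-truth function, so parameter recovery is
  measurable.
* :func:`simulate_toy_complexes` builds trigonal Pd complexes analytically --
  donor atoms at prescribed in-plane angles, the metal displaced along the
  plane normal -- so the geometric descriptors (planarity, Y-ness, projected
  metal angle) have closed-form ground truth before jitter.

Label noise can be expressed in kcal/mol of free-energy error and converted to
an equivalent S%-scale standard deviation by the delta method
(:func:`noise_sd_from_ddg_error`), since a ~1 kcal/mol energy error is the
scale at which computed selectivities become unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .features import FeatureTable
from .geometry import Role, Structure
from .selectivity import SelectivityRecord, ThermoContext

__all__ = [
    "PlantedSystem",
    "ToyComplexSpec",
    "simulate_feature_table",
    "simulate_toy_complexes",
    "random_table",
    "noise_sd_from_ddg_error",
]

# S% values are kept strictly inside (0, 100) so ratio/log metrics stay finite
_S_CLIP = (1.0, 99.0)


@dataclass(frozen=True)
class PlantedSystem:
    """Planted feature -> selectivity system mirroring the experimental regime:
    17 training ligands, 10 + 3 validation ligands, 15 features, three
    informative features combined through a hinge nonlinearity, and label
    noise of a few S-percentage points."""

    n_train: int = 17
    n_val1: int = 10
    n_val2: int = 3
    n_features: int = 15
    informative_indices: tuple[int, ...] = (0, 1, 2)
    coefficients: tuple[float, ...] = (30.0, -25.0, 20.0)
    nonlinearity: str = "hinge"  # hinge | interaction | none
    noise_sd_S_percent: float = 4.0
    baseline_s: float = 50.0  # latent S% at the hinge knots; >50 models an S-selective family
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 <= i < self.n_features for i in self.informative_indices):
            raise ValueError("informative indices out of feature range")
        if len(self.coefficients) != len(self.informative_indices):
            raise ValueError("one coefficient per informative feature")
        if self.noise_sd_S_percent < 0:
            raise ValueError("noise sd must be non-negative")
        if self.nonlinearity not in ("hinge", "interaction", "none"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if min(self.n_train, self.n_val1, self.n_val2) < 1:
            raise ValueError("all split sizes must be >= 1")


def _feature_names(sys: PlantedSystem) -> tuple[list[str], dict[str, str]]:
    # informative features are named after the kinds of factors that matter in
    # the real system (electronics at C2, metal planarity, a ring-junction
    # angle); this is a naming convention only, with no chemical content.
    names = [f"f{i + 1:02d}" for i in range(sys.n_features)]
    prov = {n: "other" for n in names}
    themed = [
        ("c2_electron_population", "electronic"),
        ("pd_planarity", "geometric"),
        ("ring_junction_angle", "geometric"),
    ]
    for slot, idx in enumerate(sys.informative_indices[: len(themed)]):
        old = names[idx]
        del prov[old]
        names[idx], tag = themed[slot]
        prov[names[idx]] = tag
    return names, prov


def _latent_fn(sys: PlantedSystem) -> Callable[[np.ndarray], np.ndarray]:
    idx = np.asarray(sys.informative_indices, dtype=int)
    a = np.asarray(sys.coefficients, dtype=float)

    def latent(x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        f = x[:, idx]
        if sys.nonlinearity == "hinge":
            # kinked-linear hinge (MARS-style): slope 1 below the knot at 0.5,
            # slope 2 above -- a monotone, saturating-accelerating trend
            g = (f - 0.5) + np.maximum(0.0, f - 0.5)
        elif sys.nonlinearity == "none":
            g = f - 0.5
        else:  # interaction: centred products of cyclically-next informative pairs
            nxt = np.roll(np.arange(len(idx)), -1)
            g = 4.0 * (f - 0.5) * (x[:, idx[nxt]] - 0.5)
        return np.clip(sys.baseline_s + g @ a, *_S_CLIP)

    return latent


def simulate_feature_table(
    sys: PlantedSystem | None = None,
) -> tuple[FeatureTable, FeatureTable, FeatureTable, Callable[[np.ndarray], np.ndarray]]:
    """Generate (train, val1, val2) labelled tables plus the ground-truth map.

    Features are uniform on [0, 1]; the latent S% is
    ``clip(50 + sum_i a_i g_i(f), 1, 99)`` and the observed S% adds Gaussian
    noise (clipped back into the valid range).  Same seed, same tables.
    """
    sys = sys or PlantedSystem()
    rng = np.random.default_rng(sys.seed)
    latent = _latent_fn(sys)
    names, prov = _feature_names(sys)

    tables = []
    counts = (sys.n_train, sys.n_val1, sys.n_val2)
    prefixes = ("L", "V", "W")
    for count, prefix in zip(counts, prefixes):
        x = rng.uniform(0.0, 1.0, size=(count, sys.n_features))
        s_true = latent(x)
        noise = rng.normal(0.0, sys.noise_sd_S_percent, size=count)
        s_obs = np.clip(s_true + noise, *_S_CLIP)
        ids = [f"{prefix}{i + 1:02d}" for i in range(count)]
        df = pd.DataFrame(x, index=ids, columns=names)
        labels = {
            i: SelectivityRecord(s_percent=float(s), r_percent=float(100.0 - s))
            for i, s in zip(ids, s_obs)
        }
        tables.append(FeatureTable(df, dict(prov), labels))
    return tables[0], tables[1], tables[2], latent


def random_table(
    n: int,
    p: int,
    label_range: tuple[float, float] = (0.0, 100.0),
    seed: int = 0,
) -> FeatureTable:
    """Fully random labelled table: features uniform on [0, 1], S% labels
    uniform on ``label_range`` (clipped to the open (0, 100) interval so the
    record invariants hold)."""
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=(n, p))
    s = np.clip(rng.uniform(*label_range, size=n), 0.05, 99.95)
    ids = [f"R{i + 1:03d}" for i in range(n)]
    df = pd.DataFrame(x, index=ids, columns=[f"f{j + 1:02d}" for j in range(p)])
    labels = {
        i: SelectivityRecord(s_percent=float(v), r_percent=float(100.0 - v))
        for i, v in zip(ids, s)
    }
    return FeatureTable(df, {}, labels)


def noise_sd_from_ddg_error(
    sigma_kcal: float,
    reference: SelectivityRecord,
    ctx: ThermoContext | None = None,
) -> float:
    """S%-scale standard deviation equivalent to a free-energy error.

    First-order (delta-method) propagation of ddG = R T ln(p/(1-p)) at a
    reference composition: sd(S%) ~= 100 * p * (1-p) / (R T) * sigma, with p
    the S fraction.  At 80:20 and 298.15 K, 1 kcal/mol maps to ~27 S%-points,
    which is why raw computed energies resolve selectivity so poorly.
    """
    ctx = ctx or ThermoContext()
    p = reference.s_percent / 100.0
    return 100.0 * p * (1.0 - p) / ctx.rt * sigma_kcal


# ---------------------------------------------------------------------------
# Toy trigonal complexes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyComplexSpec:
    """Analytic trigonal Pd complex: three donors at prescribed in-plane
    angles (summing to 360 deg), the metal offset along the plane normal."""

    donor_angles: tuple[float, float, float] = (120.0, 120.0, 120.0)
    pd_offset: float = 0.3          # A along the donor-plane normal
    p_donor_distance: float = 2.3   # Pd-P distance projected in plane, A
    c_donor_distance: float = 2.1   # Pd-C distances projected in plane, A
    jitter_sd: float = 0.0          # Gaussian coordinate jitter, A
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.donor_angles):
            raise ValueError("donor angles must be positive")
        if abs(sum(self.donor_angles) - 360.0) > 1e-9:
            raise ValueError("donor angles must sum to 360 degrees")
        if self.p_donor_distance <= 0 or self.c_donor_distance <= 0:
            raise ValueError("donor distances must be positive")
        if self.pd_offset < 0 or self.jitter_sd < 0:
            raise ValueError("pd_offset and jitter_sd must be non-negative")

    def true_descriptors(self) -> dict[str, float | None]:
        """Closed-form descriptor values before jitter."""
        y = sum(abs(a - 120.0) for a in self.donor_angles)
        if self.pd_offset > 0:
            # Pd->P = (p_dist, 0, -off); Pd->foot = (0, 0, -off)
            angle = float(np.degrees(np.arctan2(self.p_donor_distance, self.pd_offset)))
        else:
            angle = None
        return {
            "planarity": self.pd_offset,
            "y_ness": y,
            "projected_metal_angle": angle,
        }


def _build_complex(spec: ToyComplexSpec, ligand_id: str, role: Role,
                   rng: np.random.Generator) -> Structure:
    a1, a2, _ = spec.donor_angles
    theta = np.radians([0.0, a1, a1 + a2])
    dist = np.array([spec.p_donor_distance,
                     spec.c_donor_distance, spec.c_donor_distance])
    donors = np.stack(
        [dist * np.cos(theta), dist * np.sin(theta), np.zeros(3)], axis=1
    )
    z = spec.pd_offset if role is Role.pro_R else -spec.pd_offset
    coords = np.vstack([[0.0, 0.0, z], donors])
    if spec.jitter_sd > 0:
        coords = coords + rng.normal(0.0, spec.jitter_sd, size=coords.shape)
    return Structure(
        ["Pd", "P", "C", "C"], coords, ligand_id=ligand_id, role=role,
        comment=f"ligand={ligand_id} role={role.value} synthetic toy complex",
    )


def simulate_toy_complexes(
    spec: ToyComplexSpec, n: int = 1
) -> tuple[list[tuple[Structure, Structure]], dict[str, float | None]]:
    """``n`` jittered (pro_R, pro_S) pairs plus the pre-jitter analytic
    descriptor values (identical for every pair; the pro_S structure is the
    mirror image through the donor plane, which leaves all descriptors
    unchanged).  Atom order: Pd, P, C, C -- so DonorSet(0, (1, 2, 3), 1)."""
    rng = np.random.default_rng(spec.seed)
    pairs = []
    for i in range(n):
        lid = f"T{i + 1:02d}"
        pairs.append(
            (_build_complex(spec, lid, Role.pro_R, rng),
             _build_complex(spec, lid, Role.pro_S, rng))
        )
    return pairs, spec.true_descriptors()
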