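"""Solvent-exposure analysis of ribosomal protein chains.

Computes solvent-accessible surface area (SASA) with the Shrake-Rupley
method on a deterministic spherical Fibonacci lattice, derives each chain's
solvent-exposed fraction (in-complex SASA over isolated-chain SASA), and
tests whether heterogeneous RPs are more exposed than the rest of the
assembly (Mann-Whitney).

The exposed fraction expresses "total surface area minus all interface
areas" as a ratio: the SASA a chain retains inside the full assembly,
divided by the SASA it would have in isolation.  A chain with no contacts
has fraction 1; a fully buried chain has fraction 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import TestResult, mann_whitney

__all__ = [
    "AtomSet",
    "ChainExposure",
    "VDW_RADII",
    "fibonacci_sphere",
    "shrake_rupley_sasa",
    "exposed_fraction",
    "chain_exposures",
    "map_chains_to_rps",
    "exposure_enrichment",
]

# Van der Waals radii in Angstrom; elements not listed fall back to DEFAULT_RADIUS.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_RADIUS = 1.70


@dataclass
class AtomSet:
    """Atoms of a (possibly multi-chain) assembly.

    Parallel arrays; coordinates in Angstrom, radii are van der Waals radii.
    """

    chain_id: np.ndarray
    residue_name: np.ndarray
    residue_number: np.ndarray
    element: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.residue_number = np.asarray(self.residue_number, dtype=int)
        self.element = np.asarray(self.element, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=float)
        n = self.xyz.shape[0]
        for name in ("chain_id", "residue_name", "residue_number", "element",
                     "radius"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"AtomSet field {name} length mismatch")
        if n and (not np.all(np.isfinite(self.xyz)) or np.any(self.radius <= 0)):
            raise ValueError("AtomSet requires finite coordinates and radii > 0")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def subset(self, mask: np.ndarray) -> "AtomSet":
        return AtomSet(self.chain_id[mask], self.residue_name[mask],
                       self.residue_number[mask], self.element[mask],
                       self.xyz[mask], self.radius[mask])

    def select_chain(self, chain_id: str) -> "AtomSet":
        mask = self.chain_id == chain_id
        if not np.any(mask):
            raise ValueError(f"chain {chain_id!r} not present in AtomSet")
        return self.subset(mask)


@dataclass
class ChainExposure:
    chain_id: str
    rp_id: str | None
    sasa_isolated: float
    sasa_in_complex: float

    @property
    def exposed_fraction(self) -> float:
        return self.sasa_in_complex / self.sasa_isolated


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the sphere (n_points x 3)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    i = np.arange(n_points, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_points
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _grid_neighbors(xyz: np.ndarray,
                    cell: float) -> tuple[dict[tuple, np.ndarray], np.ndarray]:
    keys = np.floor(xyz / cell).astype(int)
    buckets: dict[tuple, list[int]] = {}
    for idx, key in enumerate(map(tuple, keys)):
        buckets.setdefault(key, []).append(idx)
    return {k: np.asarray(v) for k, v in buckets.items()}, keys


def shrake_rupley_sasa(atoms: AtomSet, probe: float = 1.4,
                       n_points: int = 960) -> tuple[np.ndarray, dict[str, float]]:
    """Per-atom and per-chain SASA by Shrake-Rupley.

    A lattice of ``n_points`` test points is placed on each atom's
    probe-inflated sphere of radius r + probe; a point is accessible iff it
    lies outside every other atom's inflated sphere.  Neighbor lookup uses a
    spatial hash grid with cell size 2 * (r_max + probe).
    """
    if len(atoms) == 0:
        raise ValueError("cannot compute SASA of an empty AtomSet")
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    unit = fibonacci_sphere(n_points)
    big_r = atoms.radius + probe
    cell = 2.0 * (atoms.radius.max() + probe)
    buckets, keys = _grid_neighbors(atoms.xyz, cell)
    offsets = np.array([(dx, dy, dz) for dx in (-1, 0, 1)
                        for dy in (-1, 0, 1) for dz in (-1, 0, 1)])
    sasa = np.empty(len(atoms))
    for i in range(len(atoms)):
        cand: list[np.ndarray] = []
        for off in offsets:
            got = buckets.get(tuple(keys[i] + off))
            if got is not None:
                cand.append(got)
        neigh = np.concatenate(cand)
        neigh = neigh[neigh != i]
        if neigh.size:
            delta = atoms.xyz[neigh] - atoms.xyz[i]
            dist2 = np.einsum("ij,ij->i", delta, delta)
            close = dist2 < (big_r[i] + big_r[neigh]) ** 2
            neigh = neigh[close]
        if neigh.size == 0:
            sasa[i] = 4.0 * np.pi * big_r[i] ** 2
            continue
        pts = atoms.xyz[i] + big_r[i] * unit
        diff = pts[:, None, :] - atoms.xyz[neigh][None, :, :]
        d2 = np.einsum("pnk,pnk->pn", diff, diff)
        buried = np.any(d2 < big_r[neigh][None, :] ** 2, axis=1)
        frac = 1.0 - buried.mean()
        sasa[i] = 4.0 * np.pi * big_r[i] ** 2 * frac
    per_chain: dict[str, float] = {}
    for c in atoms.chains:
        per_chain[c] = float(sasa[atoms.chain_id == c].sum())
    return sasa, per_chain


def exposed_fraction(atoms: AtomSet, chain_id: str, probe: float = 1.4,
                     n_points: int = 960,
                     rp_id: str | None = None) -> ChainExposure:
    """Solvent-exposed fraction of one chain within the full assembly."""
    chain = atoms.select_chain(chain_id)
    _, iso = shrake_rupley_sasa(chain, probe=probe, n_points=n_points)
    _, cplx = shrake_rupley_sasa(atoms, probe=probe, n_points=n_points)
    return ChainExposure(chain_id, rp_id, iso[chain_id], cplx[chain_id])


def chain_exposures(atoms: AtomSet, probe: float = 1.4,
                    n_points: int = 960) -> pd.DataFrame:
    """Exposure of every chain: one full-assembly pass plus per-chain isolated passes."""
    _, cplx = shrake_rupley_sasa(atoms, probe=probe, n_points=n_points)
    rows = []
    for c in atoms.chains:
        _, iso = shrake_rupley_sasa(atoms.select_chain(c), probe=probe,
                                    n_points=n_points)
        rows.append({"chain_id": c, "sasa_isolated": iso[c],
                     "sasa_in_complex": cplx[c],
                     "exposed_fraction": cplx[c] / iso[c]})
    return pd.DataFrame(rows)


def map_chains_to_rps(exposures: pd.DataFrame,
                      chain_map: pd.DataFrame) -> pd.DataFrame:
    """Attach rp_id to mapped chains; unmapped chains (rRNA, factors) are dropped
    from the result but have already acted as occluders during SASA.

    ``chain_map`` needs columns chain_id, rp_id.  A mapping that references a
    chain absent from ``exposures`` is an error.
    """
    for col in ("chain_id", "rp_id"):
        if col not in chain_map.columns:
            raise ValueError(f"chain map missing column {col!r}")
    missing = set(chain_map["chain_id"]) - set(exposures["chain_id"])
    if missing:
        raise ValueError(f"chain map references absent chains: {sorted(missing)}")
    out = exposures.merge(chain_map[["chain_id", "rp_id"]], on="chain_id",
                          how="inner")
    return out.reset_index(drop=True)


def exposure_enrichment(exposures: pd.DataFrame,
                        heterogeneous: set[str]) -> TestResult:
    """Mann-Whitney comparison of exposed fractions: heterogeneous vs other RPs."""
    if "rp_id" not in exposures.columns:
        raise ValueError("exposures must carry rp_id (run map_chains_to_rps)")
    het = exposures.loc[exposures["rp_id"].isin(heterogeneous),
                        "exposed_fraction"].to_numpy()
    rest = exposures.loc[~exposures["rp_id"].isin(heterogeneous),
                         "exposed_fraction"].to_numpy()
    if het.size == 0 or rest.size == 0:
        raise ValueError("both groups must be non-empty for enrichment test")
    res = mann_whitney(het, rest)
    res.extra["median_heterogeneous"] = float(np.median(het))
    res.extra["median_other"] = float(np.median(rest))
    return res
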