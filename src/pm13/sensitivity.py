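"""Score sensitivity to geometric and chemical perturbation of a groove.

Two controlled perturbations probe what the PM13 score responds to:

* geometry — every atom is displaced by an i.i.d. Gaussian field that is
  rescaled so the in-frame RMSD to the original pocket hits an exact
  target (no re-superposition); group types are untouched, so descriptor
  bin occupancies are preserved and only the distance values move;
* chemistry — a chosen fraction of atoms gets a uniformly random *different*
  group type while coordinates stay fixed, so the pooled multiset of
  distances is preserved and only their partition over bins changes.

``sensitivity_curve`` builds an ensemble of geometry-perturbed copies with
target RMSDs drawn uniformly up to a maximum (5 Å by default) and scores
each against the original at several match thresholds, yielding a tidy
table from which score-decay curves can be plotted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accessibility import Pocket
from .atom_typing import GROUP_TYPES, TypedAtom, group_radius
from .descriptor import build_descriptor, compare_pockets
from .errors import InputError

DEFAULT_THRESHOLDS = (0.125, 0.25, 0.5, 0.75, 1.0)  # Å


@dataclass
class PerturbationRun:
    seed: int
    n_members: int
    max_rmsd: float
    thresholds: tuple[float, ...]
    table: pd.DataFrame  # columns: member, rmsd, threshold, pms_min, pms_max


def _with_coords(pocket: Pocket, coords: np.ndarray) -> Pocket:
    atoms = [TypedAtom(float(x), float(y), float(z), a.group, a.radius,
                       chain=a.chain, res_name=a.res_name, res_seq=a.res_seq,
                       atom_name=a.atom_name)
             for a, (x, y, z) in zip(pocket.atoms, coords)]
    return Pocket(pocket.kind, atoms, pocket.source)


def perturb_to_rmsd(pocket: Pocket, target_rmsd: float,
                    seed: int) -> tuple[Pocket, float]:
    """Gaussian-displace every atom, rescaled to an exact in-frame RMSD."""
    if target_rmsd < 0:
        raise InputError("target RMSD must be non-negative")
    coords = pocket.coords()
    if target_rmsd == 0:
        return _with_coords(pocket, coords), 0.0
    rng = np.random.default_rng(seed)
    disp = rng.normal(size=coords.shape)
    scale = target_rmsd / np.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
    moved = coords + disp * scale
    achieved = float(np.sqrt(np.mean(np.sum((moved - coords) ** 2, axis=1))))
    return _with_coords(pocket, moved), achieved


def relabel_types(pocket: Pocket, fraction: float, seed: int) -> Pocket:
    """Re-assign ⌊fraction·n⌋ atoms (chosen without replacement) to a
    uniformly random different group type; coordinates untouched."""
    if not 0.0 <= fraction <= 1.0:
        raise InputError("fraction must lie in [0, 1]")
    n = len(pocket)
    k = int(fraction * n)
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=k, replace=False)) if k else set()
    atoms = []
    for i, a in enumerate(pocket.atoms):
        if i in chosen:
            others = [g for g in GROUP_TYPES if g != a.group]
            new = others[rng.integers(len(others))]
            atoms.append(TypedAtom(a.x, a.y, a.z, new, group_radius(new),
                                   chain=a.chain, res_name=a.res_name,
                                   res_seq=a.res_seq, atom_name=a.atom_name))
        else:
            atoms.append(a)
    return Pocket(pocket.kind, atoms, pocket.source)


def sensitivity_curve(pocket: Pocket, n_members: int = 1000,
                      max_rmsd: float = 5.0,
                      thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                      seed: int = 0) -> PerturbationRun:
    """Score an ensemble of geometry-perturbed copies against the original.

    Target RMSDs are drawn uniformly on (0, max_rmsd]; every member is
    scored at every threshold.
    """
    if n_members < 1:
        raise InputError("need at least one ensemble member")
    rng = np.random.default_rng(seed)
    original = build_descriptor(pocket)
    rows = []
    for member in range(n_members):
        target = max_rmsd * (1.0 - rng.random())  # uniform on (0, max]
        member_seed = int(rng.integers(2 ** 31))
        perturbed, achieved = perturb_to_rmsd(pocket, target, member_seed)
        desc = build_descriptor(perturbed)
        for t in thresholds:
            s = compare_pockets(original, desc, t)
            rows.append((member, achieved, t, s.pms_min, s.pms_max))
    table = pd.DataFrame(rows, columns=["member", "rmsd", "threshold",
                                        "pms_min", "pms_max"])
    return PerturbationRun(seed, n_members, max_rmsd, tuple(thresholds), table)


def relabel_curve(pocket: Pocket, fractions=None, n_seeds: int = 20,
                  thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                  seed: int = 0) -> pd.DataFrame:
    """Score randomly relabelled copies against the original for a grid of
    relabelled fractions (tidy table: fraction, seed, threshold, scores)."""
    if fractions is None:
        fractions = np.linspace(0.0, 1.0, 11)
    rng = np.random.default_rng(seed)
    original = build_descriptor(pocket)
    rows = []
    for frac in fractions:
        for _ in range(n_seeds):
            s_i = int(rng.integers(2 ** 31))
            desc = build_descriptor(relabel_types(pocket, float(frac), s_i))
            for t in thresholds:
                s = compare_pockets(original, desc, t)
                rows.append((float(frac), s_i, t, s.pms_min, s.pms_max))
    return pd.DataFrame(rows, columns=["fraction", "seed", "threshold",
                                       "pms_min", "pms_max"])


def binned_mean_scores(run: PerturbationRun, threshold: float = 0.5,
                       bin_width: float = 1.0) -> pd.Series:
    """Mean PMSMin per RMSD bin ([0,1), [1,2), … by default) at one
    threshold — the summary behind the score-decay curves."""
    sub = run.table[np.isclose(run.table["threshold"], threshold)]
    bins = (sub["rmsd"] // bin_width).astype(int)
    return sub.groupby(bins)["pms_min"].mean()
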