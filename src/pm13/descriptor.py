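"""The PM13 sorted-distance descriptor and pocket similarity scores.

A pocket of n typed atoms is summarized by its n(n−1)/2 intra-site
distances, partitioned by the unordered pair of ProtOr group types of the
two endpoints. With 13 types there are 13·12/2 + 13 = 91 such pairs, so the
descriptor is 91 sorted (non-decreasing) distance lists. The descriptor is
rigid-motion invariant by construction.

Two pockets are compared list-by-list: corresponding lists are swept with a
greedy two-pointer alignment in which a pair of distances matches if they
differ by at most a threshold (0.5 Å by default), each element matching at
most once. On sorted lists this greedy sweep attains the maximum bipartite
matching size (interval compatibility; verified by a property test against
an exact matching oracle, not assumed). The cumulative match count over the
91 lists, divided by the total distance count of the larger or smaller
site, gives PMSMin and PMSMax respectively; the headline PM13 score is
PMSMin.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .accessibility import Pocket
from .atom_typing import GROUP_INDEX, GROUP_TYPES
from .errors import ContractError, DescriptorError, InputError

N_TYPES = len(GROUP_TYPES)
N_BINS = N_TYPES * (N_TYPES - 1) // 2 + N_TYPES  # 91
DEFAULT_THRESHOLD = 0.5  # Å


def pair_bin_index(a: str, b: str) -> int:
    """Bin id in [0, 90] of an unordered group-type pair (symmetric,
    bijective over the 91 unordered pairs including same-type pairs)."""
    i, j = sorted((GROUP_INDEX[a], GROUP_INDEX[b]))
    return i * N_TYPES - i * (i - 1) // 2 + (j - i)


@dataclass
class PocketDescriptor:
    """91 sorted distance lists keyed by unordered type pair."""

    lists: list[np.ndarray]
    n_atoms: int
    source: str = ""

    @property
    def n_distances(self) -> int:
        return self.n_atoms * (self.n_atoms - 1) // 2

    def validate(self) -> None:
        if len(self.lists) != N_BINS:
            raise ContractError(f"descriptor has {len(self.lists)} bins, not {N_BINS}")
        if sum(len(v) for v in self.lists) != self.n_distances:
            raise ContractError("bin lengths do not sum to n(n-1)/2")
        for v in self.lists:
            if len(v) and (np.any(np.diff(v) < 0) or v[0] <= 0):
                raise ContractError("distance list unsorted or non-positive")


@dataclass
class ScorePair:
    """PMSMin/PMSMax similarity of two pockets at a given threshold."""

    pms_min: float
    pms_max: float
    matches: int
    denominators: tuple[int, int]  # (larger site, smaller site)
    threshold: float

    @property
    def pm13(self) -> float:
        """The headline PM13 score (PMSMin by convention)."""
        return self.pms_min


def build_descriptor(pocket: Pocket) -> PocketDescriptor:
    """Bin all unordered intra-pocket atom-pair distances by type pair."""
    n = len(pocket)
    if n < 3:
        raise DescriptorError(
            f"pocket {pocket.source or pocket.kind}: {n} atoms (<3)")
    coords = pocket.coords()
    groups = pocket.groups()
    dists = pdist(coords)
    bins: list[list[float]] = [[] for _ in range(N_BINS)]
    for (i, j), d in zip(itertools.combinations(range(n), 2), dists):
        bins[pair_bin_index(groups[i], groups[j])].append(float(d))
    lists = [np.sort(np.array(v)) for v in bins]
    desc = PocketDescriptor(lists, n, pocket.source)
    desc.validate()
    return desc


def count_matches(a: np.ndarray, b: np.ndarray,
                  threshold: float = DEFAULT_THRESHOLD) -> int:
    """Greedy two-pointer alignment of two sorted lists; counts pairs whose
    distances differ by at most ``threshold``, each element used once."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (len(a) and np.any(np.diff(a) < 0)) or (len(b) and np.any(np.diff(b) < 0)):
        raise ContractError("count_matches requires sorted inputs")
    i = j = count = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= threshold:
            count += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return count


def _as_descriptor(p: Pocket | PocketDescriptor) -> PocketDescriptor:
    if isinstance(p, PocketDescriptor):
        return p  # validated at construction
    return build_descriptor(p)


def compare_pockets(pa: Pocket | PocketDescriptor, pb: Pocket | PocketDescriptor,
                    threshold: float = DEFAULT_THRESHOLD) -> ScorePair:
    """Score a pocket pair: cumulative matches over the 91 corresponding
    lists, divided by the larger (PMSMin) / smaller (PMSMax) site's total
    distance count."""
    da, db = _as_descriptor(pa), _as_descriptor(pb)
    if da.n_distances == 0 or db.n_distances == 0:
        raise DescriptorError("cannot compare an empty descriptor")
    matches = sum(count_matches(la, lb, threshold)
                  for la, lb in zip(da.lists, db.lists))
    larger = max(da.n_distances, db.n_distances)
    smaller = min(da.n_distances, db.n_distances)
    return ScorePair(matches / larger, matches / smaller, matches,
                     (larger, smaller), threshold)


@dataclass
class ScoreMatrix:
    labels: list[str]
    pms_min: np.ndarray
    pms_max: np.ndarray
    threshold: float


def all_vs_all(pockets: list[tuple[str, Pocket]],
               threshold: float = DEFAULT_THRESHOLD) -> ScoreMatrix:
    """Symmetric all-against-all PM13 score matrix over same-kind pockets."""
    if len(pockets) < 2:
        raise InputError("need at least two pockets")
    kinds = {p.kind for _, p in pockets}
    if len(kinds) > 1:
        raise InputError(f"mixed pocket kinds: {sorted(kinds)}")
    labels = [lab for lab, _ in pockets]
    descs = [build_descriptor(p) for _, p in pockets]
    n = len(descs)
    mn = np.eye(n)
    mx = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = compare_pockets(descs[i], descs[j], threshold)
            mn[i, j] = mn[j, i] = s.pms_min
            mx[i, j] = mx[j, i] = s.pms_max
    return ScoreMatrix(labels, mn, mx, threshold)
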