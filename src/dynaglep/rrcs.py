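"""Residue–residue contact scores (RRCS), ΔRRCS state calls and conformer selection.

The RRCS between two residues is a sum over their heavy-atom cross pairs of a
piecewise-linear distance kernel: an atom pair contributes 1 below ``d_full``,
0 above ``d_zero`` and interpolates linearly in between.  Tracking a handful of
activation-microswitch residue pairs (defaults ``3x43–7x49``, ``3x43–7x53``,
``3x46–7x53``, ``3x50–7x53``, the TM3–TM7 packing that rearranges on Class A
GPCR activation) across a trajectory, and normalizing each frame's score by the
score of a reference activated conformation, yields a per-frame, per-pair ratio
profile: ratios above 1 favour the active arrangement, below 1 the inactive one.

On top of the profiles this module provides frame filtering (RMSD-convergence
and profile-duplicate removal) and deterministic selection of a nonredundant,
state-balanced set of representative conformations by farthest-point sampling
in ΔRRCS space.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .conformers_io import BWMap, ConformationEnsemble, Frame

logger = logging.getLogger(__name__)

#: TM3–TM7 activation-microswitch pairs used by default (BW numbering).
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("3x43", "7x49"),
    ("3x43", "7x53"),
    ("3x46", "7x53"),
    ("3x50", "7x53"),
)


@dataclass(frozen=True)
class RRCSKernelParams:
    """Distance kernel constants (Å): full contact below d_full, none above d_zero."""

    d_full: float = 3.23
    d_zero: float = 4.63

    def __post_init__(self):
        if not (0 < self.d_full < self.d_zero):
            raise ValueError("require 0 < d_full < d_zero")


@dataclass(frozen=True)
class ResiduePairSpec:
    bw_a: str
    bw_b: str

    def __post_init__(self):
        if self.bw_a == self.bw_b:
            raise ValueError("a residue pair needs two distinct residues")

    def __str__(self) -> str:
        return f"{self.bw_a}:{self.bw_b}"


def parse_pairs(text: str) -> list[ResiduePairSpec]:
    """Parse ``"3x43:7x49,3x43:7x53"`` into pair specs."""
    pairs = []
    for token in text.split(","):
        a, b = token.strip().split(":")
        pairs.append(ResiduePairSpec(a, b))
    return pairs


@dataclass
class DeltaRRCSProfile:
    """Raw and reference-normalized contact scores, frames × pairs."""

    frame_ids: np.ndarray
    pairs: list[ResiduePairSpec]
    raw: np.ndarray
    reference_raw: np.ndarray
    normalized: np.ndarray          # NaN where undefined
    defined_mask: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.raw.shape[0]

    def vectors(self) -> np.ndarray:
        """Normalized profiles with undefined entries zero-filled (for geometry)."""
        v = self.normalized.copy()
        v[~self.defined_mask] = 0.0
        return v


@dataclass
class StateCall:
    """Per-pair and aggregated per-frame activation-state calls."""

    per_pair: np.ndarray   # (frames, pairs) of {"active", "inactive", "neutral", "undefined"}
    frame_call: np.ndarray  # (frames,) of {"active", "inactive", "intermediate", "undefined"}


def residue_contact_score(atoms_a: np.ndarray, atoms_b: np.ndarray,
                          k: RRCSKernelParams = RRCSKernelParams()) -> float:
    """Contact score between two heavy-atom coordinate sets.

    Sum over all cross pairs of the piecewise-linear kernel; symmetric in its
    arguments and non-increasing as the residues move apart.
    """
    atoms_a = np.atleast_2d(np.asarray(atoms_a, dtype=float))
    atoms_b = np.atleast_2d(np.asarray(atoms_b, dtype=float))
    if atoms_a.size == 0 or atoms_b.size == 0:
        raise ValueError("residue_contact_score requires non-empty atom sets")
    d = np.linalg.norm(atoms_a[:, None, :] - atoms_b[None, :, :], axis=-1)
    contrib = np.clip((k.d_zero - d) / (k.d_zero - k.d_full), 0.0, 1.0)
    # fsum is correctly rounded, so the score is exactly symmetric in (a, b)
    return math.fsum(contrib.ravel())


#: Reference scores below this are treated as no-contact: the ratio is undefined.
REFERENCE_EPS = 1e-9


def delta_rrcs(ensemble: ConformationEnsemble,
               pairs: list[ResiduePairSpec],
               reference: Frame,
               bw_map: BWMap,
               k: RRCSKernelParams = RRCSKernelParams(),
               mode: str = "ratio") -> DeltaRRCSProfile:
    """Per-frame contact scores for each pair, normalized to a reference frame.

    The reference is the initial activated conformation; its own normalized row
    is exactly 1 for every defined pair.  Pairs whose reference score is below
    ``REFERENCE_EPS`` are flagged undefined rather than divided.

    ``mode="ratio"`` (default) divides by the reference score — the activation
    threshold of 1 lives on this scale.  ``mode="difference"`` subtracts the
    reference instead (exploratory; the threshold rule does not apply there,
    and the reference row is 0 rather than 1).
    """
    if mode not in ("ratio", "difference"):
        raise ValueError("mode must be 'ratio' or 'difference'")
    resolved = []
    for p in pairs:
        ca, sa = bw_map.residue(p.bw_a)
        cb, sb = bw_map.residue(p.bw_b)
        resolved.append(((ca, sa), (cb, sb)))

    def _scores(frame: Frame) -> np.ndarray:
        out = np.empty(len(pairs))
        for j, ((ca, sa), (cb, sb)) in enumerate(resolved):
            out[j] = residue_contact_score(frame.residue_atoms(ca, sa),
                                           frame.residue_atoms(cb, sb), k)
        return out

    reference_raw = _scores(reference)
    raw = np.stack([_scores(fr) for fr in ensemble.frames])
    if mode == "difference":
        defined = np.ones(len(pairs), dtype=bool)
        normalized = raw - reference_raw[None, :]
    else:
        defined = reference_raw >= REFERENCE_EPS
        normalized = np.full_like(raw, np.nan)
        normalized[:, defined] = raw[:, defined] / reference_raw[defined]
    if not defined.all():
        bad = [str(pairs[j]) for j in np.flatnonzero(~defined)]
        logger.warning("pairs %s have no contact in the reference; ratios undefined", bad)
    mask = np.broadcast_to(defined, raw.shape).copy()
    return DeltaRRCSProfile(
        frame_ids=np.array([fr.frame_id for fr in ensemble.frames]),
        pairs=list(pairs), raw=raw, reference_raw=reference_raw,
        normalized=normalized, defined_mask=mask,
    )


def call_state(profile: DeltaRRCSProfile, threshold: float = 1.0) -> StateCall:
    """Classify each frame as active / inactive / intermediate from its profile.

    A pair with normalized score strictly above `threshold` favours the active
    conformation; strictly below favours the inactive one; exactly at threshold
    it is neutral and does not vote.  The frame call is the majority over voting
    pairs, with an exact tie (including the all-neutral reference frame itself)
    called intermediate.
    """
    n_f, n_p = profile.normalized.shape
    per_pair = np.full((n_f, n_p), "undefined", dtype=object)
    defined = profile.defined_mask
    with np.errstate(invalid="ignore"):
        per_pair[defined & (profile.normalized > threshold)] = "active"
        per_pair[defined & (profile.normalized < threshold)] = "inactive"
        per_pair[defined & (profile.normalized == threshold)] = "neutral"
    frame_call = np.empty(n_f, dtype=object)
    for i in range(n_f):
        if not defined[i].any():
            frame_call[i] = "undefined"
            warnings.warn(f"frame {profile.frame_ids[i]}: all pairs undefined", stacklevel=2)
            continue
        n_act = int((per_pair[i] == "active").sum())
        n_inact = int((per_pair[i] == "inactive").sum())
        if n_act > n_inact:
            frame_call[i] = "active"
        elif n_inact > n_act:
            frame_call[i] = "inactive"
        else:
            frame_call[i] = "intermediate"
    return StateCall(per_pair=per_pair, frame_call=frame_call)


@dataclass(frozen=True)
class FilterParams:
    """Frame-filter settings: trailing RMSD window and profile rounding."""

    rmsd_window: int = 20
    rmsd_mad_factor: float = 5.0
    profile_decimals: int = 3


def filter_frames(ensemble: ConformationEnsemble,
                  profile: DeltaRRCSProfile,
                  rmsd_series: np.ndarray,
                  params: FilterParams = FilterParams(),
                  pocket_filter=None) -> np.ndarray:
    """Indices of frames retained after convergence and redundancy filtering.

    Three passes, in order: (1) drop frames whose backbone RMSD to the reference
    deviates from the trailing-window median by more than ``rmsd_mad_factor``
    window-MADs (frames earlier than one full window are kept — no history to
    judge them against); (2) drop frames whose rounded ΔRRCS profile duplicates
    an earlier frame's; (3) apply an optional user-supplied pocket filter
    (e.g. a pocket-volume consistency check) to the survivors.
    """
    rmsd_series = np.asarray(rmsd_series, dtype=float)
    if len(rmsd_series) != len(ensemble):
        raise ValueError("rmsd_series length must equal frame count")
    w = params.rmsd_window
    if w > len(rmsd_series):
        raise ValueError(f"rmsd window {w} longer than series ({len(rmsd_series)})")

    keep = np.ones(len(ensemble), dtype=bool)
    for i in range(w, len(rmsd_series)):
        window = rmsd_series[i - w:i]
        med = np.median(window)
        mad = np.median(np.abs(window - med))
        if np.abs(rmsd_series[i] - med) > params.rmsd_mad_factor * mad:
            keep[i] = False
    n_rmsd_dropped = int((~keep).sum())

    seen: set[bytes] = set()
    vec = np.round(profile.vectors(), params.profile_decimals)
    for i in np.flatnonzero(keep):
        key = vec[i].tobytes()
        if key in seen:
            keep[i] = False
        else:
            seen.add(key)
    logger.info("frame filter: %d dropped by RMSD, %d as profile duplicates",
                n_rmsd_dropped, int((~keep).sum()) - n_rmsd_dropped)

    retained = np.flatnonzero(keep)
    if pocket_filter is not None:
        retained = np.asarray([i for i in retained if pocket_filter(ensemble.frames[i])])
    return retained


def _farthest_point(vectors: np.ndarray, n_select: int, seed_idx: int) -> list[int]:
    """Greedy farthest-point sampling; deterministic (ties → lowest index)."""
    chosen = [seed_idx]
    dmin = np.linalg.norm(vectors - vectors[seed_idx], axis=1)
    while len(chosen) < n_select:
        nxt = int(np.argmax(dmin))  # argmax takes the first maximum: ties → lowest index
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(vectors - vectors[nxt], axis=1))
    return chosen


def select_representatives(profile: DeltaRRCSProfile,
                           calls: StateCall,
                           n_target="auto",
                           profile_decimals: int = 3) -> np.ndarray:
    """Indices of a nonredundant, state-stratified representative set.

    Frames with identical rounded profiles collapse to the lowest frame_id.
    The target count is split across frame-call groups proportionally to group
    size (largest-remainder rounding, each nonempty group getting at least one
    slot when possible), and within each group frames are picked by greedy
    farthest-point sampling in normalized-ΔRRCS space, seeded at the group's
    lowest frame_id.  Deterministic given its inputs; `n_target="auto"` keeps
    every unique frame.
    """
    vec = profile.vectors()
    rounded = np.round(vec, profile_decimals)
    unique_idx: list[int] = []
    seen: set[bytes] = set()
    order = np.argsort(profile.frame_ids, kind="stable")
    for i in order:
        key = rounded[i].tobytes()
        if key not in seen:
            seen.add(key)
            unique_idx.append(int(i))
    unique_idx = sorted(unique_idx)
    n_unique = len(unique_idx)
    if n_target == "auto":
        n_target = n_unique
    n_target = int(n_target)
    if n_target >= n_unique:
        if n_target > n_unique:
            warnings.warn(f"n_target={n_target} exceeds {n_unique} unique frames; returning all",
                          stacklevel=2)
        return np.array(unique_idx)

    groups: dict[str, list[int]] = {}
    for i in unique_idx:
        groups.setdefault(str(calls.frame_call[i]), []).append(i)
    names = sorted(groups, key=lambda g: (-len(groups[g]), g))
    quota = {g: n_target * len(groups[g]) / n_unique for g in names}
    alloc = {g: min(int(np.floor(quota[g])), len(groups[g])) for g in names}
    # largest remainder, capped by group size; every nonempty group gets a slot if room
    for g in names:
        if alloc[g] == 0 and sum(alloc.values()) < n_target:
            alloc[g] = 1
    remainders = sorted(names, key=lambda g: (-(quota[g] - np.floor(quota[g])), g))
    while sum(alloc.values()) < n_target:
        progressed = False
        for g in remainders:
            if sum(alloc.values()) >= n_target:
                break
            if alloc[g] < len(groups[g]):
                alloc[g] += 1
                progressed = True
        if not progressed:
            break
    while sum(alloc.values()) > n_target:
        g = max(names, key=lambda g: alloc[g])
        alloc[g] -= 1

    selected: list[int] = []
    for g in names:
        members = groups[g]
        if alloc[g] == 0:
            continue
        sub = vec[members]
        seed_local = int(np.argmin(profile.frame_ids[members]))
        picked = _farthest_point(sub, alloc[g], seed_local)
        selected.extend(members[j] for j in picked)
    return np.array(sorted(selected))
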