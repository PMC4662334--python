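"""Observed availability: when traps are empty and animals are free.

The single-catch likelihood replaces time integrals of the hazard with exact
availability totals, because hazards are constant in time. For trap k let
a_k(t) = 1 while it is unoccupied, and for captured individual i let
v_i(t) = 1 while it is not held. Then

    A_k  = measure{t in [0,T] : a_k(t) = 1}
    U_ik = measure{t in [0,T] : v_i(t) a_k(t) = 1}

and every integral of v_i a_k h_k over the survey is h_k(x) * U_ik exactly.
Both are assembled from the observed capture and release times by interval
arithmetic: U_ik = T - |O_k| - |H_i| + |O_k ∩ H_i| where O_k are trap k's
occupied intervals and H_i individual i's held intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import SurveyDesign
from .simulate import CaptureData

Interval = tuple[float, float]


def _total_length(intervals: list[Interval]) -> float:
    return sum(e - s for s, e in intervals)


def _overlap(a: list[Interval], b: list[Interval]) -> float:
    """Total length of the intersection of two disjoint sorted interval lists."""
    out = 0.0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


@dataclass(frozen=True)
class AvailabilitySchedule:
    """Joint trap/individual availability totals derived from capture data."""

    individual_ids: tuple[int, ...]  # row order of U and omega
    A: np.ndarray  # (K,) days trap k was unoccupied
    U: np.ndarray  # (n, K) days individual i free AND trap k empty
    omega: np.ndarray  # (n, K) capture counts

    @property
    def n(self) -> int:
        return len(self.individual_ids)


def build_availability(
    data: CaptureData, design: SurveyDesign
) -> AvailabilitySchedule:
    """Compute A_k, U_ik and capture counts from timed capture records."""
    T = design.duration_T
    K = design.traps.n_traps
    ids = data.individual_ids
    row = {ident: r for r, ident in enumerate(ids)}
    n = len(ids)

    occupied: list[list[Interval]] = [[] for _ in range(K)]
    held: list[list[Interval]] = [[] for _ in range(n)]
    omega = np.zeros((n, K))
    for ev in data.events:
        occupied[ev.trap_id].append((ev.capture_time, ev.release_time))
        held[row[ev.individual_id]].append((ev.capture_time, ev.release_time))
        omega[row[ev.individual_id], ev.trap_id] += 1
    for ivs in occupied:
        ivs.sort()
    for ivs in held:
        ivs.sort()

    occ_len = np.array([_total_length(ivs) for ivs in occupied])
    A = T - occ_len
    U = np.empty((n, K))
    for r in range(n):
        h_len = _total_length(held[r])
        for k in range(K):
            U[r, k] = T - occ_len[k] - h_len + _overlap(occupied[k], held[r])
    if np.any(U < -1e-9) or np.any(A < -1e-9):
        raise ValueError("negative availability; invalid capture data")
    return AvailabilitySchedule(
        individual_ids=tuple(ids), A=A, U=np.clip(U, 0.0, T), omega=omega
    )
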