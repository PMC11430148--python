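"""Mode-aware screens: binding, competitive and cooperative comparisons.

The three-mixture design acquires DOSY peak lists for a ligand-only
mixture, a ligand+protein mixture, and a ligand+protein+known-ligand
mixture.  Which two lists are compared — and in which order — defines the
screen:

* **binding**: reference = ligand only, test = ligand + protein.  A hit
  (slower in test) is a protein binder.
* **competitive**: reference = ligand + protein + known ligand, test =
  ligand + protein.  A hit diffuses more slowly *without* the known
  ligand, i.e. it competes with it for the binding site.
* **cooperative**: reference = ligand + protein, test = ligand + protein +
  known ligand.  A hit diffuses more slowly *with* the known ligand —
  cooperative binding.

Hits are always "test diffuses slower than reference", so users never
reason about sign conventions.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .dosy import Condition, PeakList
from .pairs import (
    DEFAULT_ALPHA,
    DEFAULT_EPS_LOG,
    DEFAULT_TOL_PPM,
    Cluster,
    ClusterLabel,
    PairSet,
    classify_clusters,
    cluster_pairs,
    match_peaks,
    score_cluster,
)

__all__ = [
    "ScreenMode",
    "ScreenParams",
    "ScreenResult",
    "AssignmentTable",
    "assemble_pair",
    "run_screen",
    "annotate_hits",
]

logger = logging.getLogger(__name__)


class ScreenMode(str, enum.Enum):
    """Screen mode; each mode fixes the (reference, test) condition pair."""

    BINDING = "binding"
    COMPETITIVE = "competitive"
    COOPERATIVE = "cooperative"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def reference_condition(self) -> Condition:
        return _MODE_CONDITIONS[self][0]

    @property
    def test_condition(self) -> Condition:
        return _MODE_CONDITIONS[self][1]

    @property
    def interpretation(self) -> str:
        """Plain-language meaning of a hit in this mode."""
        return _MODE_INTERPRETATION[self]


_MODE_CONDITIONS: dict[ScreenMode, tuple[Condition, Condition]] = {
    ScreenMode.BINDING: (Condition.LIGAND_ONLY, Condition.LIGAND_PROTEIN),
    ScreenMode.COMPETITIVE: (
        Condition.LIGAND_PROTEIN_KNOWN,
        Condition.LIGAND_PROTEIN,
    ),
    ScreenMode.COOPERATIVE: (
        Condition.LIGAND_PROTEIN,
        Condition.LIGAND_PROTEIN_KNOWN,
    ),
}

_MODE_INTERPRETATION: dict[ScreenMode, str] = {
    ScreenMode.BINDING: (
        "hits diffuse more slowly with the protein present: they bind the protein"
    ),
    ScreenMode.COMPETITIVE: (
        "hits diffuse more slowly in the absence of the known ligand: they bind "
        "the protein more effectively without it and hence compete with it"
    ),
    ScreenMode.COOPERATIVE: (
        "hits diffuse more slowly in the presence of the known ligand: they bind "
        "the protein better with it, indicating cooperative binding"
    ),
}


@dataclass(frozen=True)
class ScreenParams:
    """Tunable thresholds of one screen run (all positive)."""

    tol_ppm: float = DEFAULT_TOL_PPM
    eps_log: float = DEFAULT_EPS_LOG
    alpha: float = DEFAULT_ALPHA
    significance_method: str = "normal"
    n_permutations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0 or self.eps_log <= 0:
            raise ValueError("tol_ppm and eps_log must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    def to_dict(self) -> dict:
        return {
            "tol_ppm": self.tol_ppm,
            "eps_log": self.eps_log,
            "alpha": self.alpha,
            "significance_method": self.significance_method,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class AssignmentTable:
    """Expected chemical shifts per compound, for annotating hit clusters."""

    entries: tuple[tuple[str, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate compound names in assignment table: {dupes}")

    @classmethod
    def from_dict(cls, mapping: dict[str, list[float]]) -> "AssignmentTable":
        return cls(
            entries=tuple(
                (name, tuple(float(s) for s in shifts))
                for name, shifts in mapping.items()
            )
        )


@dataclass(frozen=True)
class ScreenResult:
    """Everything one screen run produced, with full provenance."""

    mode: ScreenMode
    pair_set: PairSet
    clusters: tuple[Cluster, ...]
    params: ScreenParams
    provenance: dict = field(default_factory=dict)

    @property
    def hits(self) -> tuple[Cluster, ...]:
        """Clusters labelled slower-in-test: the mode's positive calls."""
        return tuple(
            c for c in self.clusters if c.label == ClusterLabel.SLOWER_IN_TEST
        )

    @property
    def slower_in_ref(self) -> tuple[Cluster, ...]:
        """Significant clusters in the opposite direction, always reported."""
        return tuple(
            c for c in self.clusters if c.label == ClusterLabel.SLOWER_IN_REF
        )

    def hit_table(self) -> list[dict]:
        """Cluster-level report rows (all clusters, hits first)."""
        rows = []
        order = sorted(
            range(len(self.clusters)),
            key=lambda i: (self.clusters[i].label == ClusterLabel.NO_CHANGE, i),
        )
        for i in order:
            c = self.clusters[i]
            shifts = [self.pair_set.pairs[j].shift_ppm for j in c.member_indices]
            rows.append(
                {
                    "cluster_id": i,
                    "n_members": c.n_members,
                    "mean_ppm_list": ";".join(f"{s:.3f}" for s in shifts),
                    "r": c.r,
                    "se_r": c.se_r,
                    "z": c.z,
                    "q": c.q,
                    "label": c.label.value,
                    "member_peak_ids": ";".join(
                        self.pair_set.pairs[j].ref_peak_id for j in c.member_indices
                    ),
                }
            )
        return rows

    def to_json(self) -> str:
        """Serialize the full result (used for provenance round-trips)."""
        payload = {
            "format_version": 1,
            "mode": self.mode.value,
            "params": self.params.to_dict(),
            "provenance": self.provenance,
            "pairs": [
                {
                    "shift_ppm": p.shift_ppm,
                    "d_ref": p.d_ref,
                    "d_test": p.d_test,
                    "sigma_ref": p.sigma_ref,
                    "sigma_test": p.sigma_test,
                    "ref_peak_id": p.ref_peak_id,
                    "test_peak_id": p.test_peak_id,
                }
                for p in self.pair_set.pairs
            ],
            "unmatched_ref": list(self.pair_set.unmatched_ref),
            "unmatched_test": list(self.pair_set.unmatched_test),
            "clusters": [
                {
                    "member_indices": list(c.member_indices),
                    "centroid": list(c.centroid),
                    "r": c.r,
                    "se_r": c.se_r,
                    "z": c.z,
                    "p": c.p,
                    "q": c.q,
                    "label": c.label.value,
                    "flags": list(c.flags),
                }
                for c in self.clusters
            ],
        }
        return json.dumps(payload, indent=2, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "ScreenResult":
        from .pairs import DiffusionPair  # local to avoid cycle at import time

        payload = json.loads(text)
        pair_set = PairSet(
            pairs=tuple(DiffusionPair(**p) for p in payload["pairs"]),
            unmatched_ref=tuple(payload["unmatched_ref"]),
            unmatched_test=tuple(payload["unmatched_test"]),
        )
        clusters = tuple(
            Cluster(
                member_indices=tuple(c["member_indices"]),
                centroid=tuple(c["centroid"]),
                r=c["r"],
                se_r=c["se_r"],
                z=c["z"],
                p=c["p"],
                q=c["q"],
                label=ClusterLabel(c["label"]),
                flags=tuple(c["flags"]),
            )
            for c in payload["clusters"]
        )
        return cls(
            mode=ScreenMode(payload["mode"]),
            pair_set=pair_set,
            clusters=clusters,
            params=ScreenParams(**payload["params"]),
            provenance=payload.get("provenance", {}),
        )


def assemble_pair(
    mode: ScreenMode | str, peaklists: dict[Condition, PeakList] | list[PeakList]
) -> tuple[PeakList, PeakList]:
    """Pick the (reference, test) peak lists mandated by the screen mode.

    Raises
    ------
    ValueError
        If a condition required by the mode is missing (named in the error).
    """
    mode = ScreenMode(mode)
    if not isinstance(peaklists, dict):
        peaklists = {pl.condition: pl for pl in peaklists}
    ref_cond, test_cond = _MODE_CONDITIONS[mode]
    for cond in (ref_cond, test_cond):
        if cond not in peaklists:
            raise ValueError(
                f"screen mode {mode.value!r} requires condition {cond.value!r}, "
                f"which is missing"
            )
    return peaklists[ref_cond], peaklists[test_cond]


def run_screen(
    mode: ScreenMode | str,
    peaklists: dict[Condition, PeakList] | list[PeakList],
    params: ScreenParams | None = None,
    provenance: dict | None = None,
) -> ScreenResult:
    """Run one full screen: assemble → match → cluster → score → classify.

    Deterministic given inputs and parameters.  Large amplitude
    discrepancies between matched peaks are expected under concentration
    changes and are ignored by design (diffusion, not intensity, carries
    the binding signal); zero matched pairs produces an empty result with
    a warning.
    """
    mode = ScreenMode(mode)
    params = params or ScreenParams()
    ref, test = assemble_pair(mode, peaklists)
    pair_set = match_peaks(ref, test, tol_ppm=params.tol_ppm)
    if len(pair_set) == 0:
        logger.warning("run_screen(%s): zero matched pairs", mode.value)
    clusters = cluster_pairs(pair_set, eps_log=params.eps_log)
    clusters = [score_cluster(c, pair_set) for c in clusters]
    clusters = classify_clusters(
        clusters,
        alpha=params.alpha,
        pair_set=pair_set,
        method=params.significance_method,
        n_permutations=params.n_permutations,
        seed=params.seed,
    )
    prov = {
        "mode": mode.value,
        "reference_condition": mode.reference_condition.value,
        "test_condition": mode.test_condition.value,
        "params": params.to_dict(),
        "n_ref_peaks": len(ref),
        "n_test_peaks": len(test),
        "interpretation": mode.interpretation,
    }
    if provenance:
        prov.update(provenance)
    return ScreenResult(
        mode=mode,
        pair_set=pair_set,
        clusters=tuple(clusters),
        params=params,
        provenance=prov,
    )


def annotate_hits(
    result: ScreenResult,
    assignments: AssignmentTable,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> list[dict]:
    """Annotate each hit cluster with the compounds its shifts match.

    A compound annotates a cluster when any of its expected shifts lies
    within ``tol_ppm`` of any member shift.  Several clusters may map to
    one compound (a binder's resonances can split across clusters); the
    compound-level hit list deduplicates them.  Clusters matching nothing
    are labelled ``"unassigned"``.
    """
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    report = []
    for i, c in enumerate(result.clusters):
        if c.label != ClusterLabel.SLOWER_IN_TEST:
            continue
        member_shifts = [
            result.pair_set.pairs[j].shift_ppm for j in c.member_indices
        ]
        compounds = sorted(
            name
            for name, shifts in assignments.entries
            if any(
                abs(s - ms) <= tol_ppm for s in shifts for ms in member_shifts
            )
        )
        report.append(
            {
                "cluster_id": i,
                "member_shifts_ppm": member_shifts,
                "compounds": compounds if compounds else ["unassigned"],
                "r": c.r,
                "z": c.z,
                "q": c.q,
            }
        )
    return report


def compound_hits(annotated: list[dict]) -> list[str]:
    """Deduplicated compound-level hit list from :func:`annotate_hits` rows."""
    seen: list[str] = []
    for row in annotated:
        for name in row["compounds"]:
            if name != "unassigned" and name not in seen:
                seen.append(name)
    return sorted(seen)
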