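"""Mapping spin-system chains onto the protein sequence.

A chain of consecutive unassigned spin systems is scored at each candidate
start position by the product of its per-system amino-acid-type posteriors
evaluated at the sequence's residue types (sum of log posteriors).  The
product rule treats per-position classifications as independent; it is the
natural chain-level extension of per-residue type recognition.  Scores are
normalized over all admissible placements, so the reported probability of
a placement is relative to the alternatives on this sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .lda import ClassificationResult, SubsetModelCache, posterior_auto
from .spinsys import Chain


class MappingError(ValueError):
    pass


@dataclass
class Placement:
    """One candidate location of a chain on the sequence (1-based start)."""

    chain: str
    start: int
    log_score: float
    norm_prob: float = 0.0
    admissible: bool = True
    reason: str = ""


PosteriorLike = Union[ClassificationResult, Mapping[str, float]]


def _prob(p: PosteriorLike, res_type: str) -> float:
    if isinstance(p, ClassificationResult):
        return p.posteriors.get(res_type, 0.0)
    return p.get(res_type, 0.0)


def score_placement(
    posteriors: Sequence[PosteriorLike],
    sequence: str,
    start: int,
    floor: float = 0.0,
) -> float:
    """Sum of log posteriors of the chain placed at ``start`` (1-based).

    A zero posterior at any position gives -inf (the placement is
    inadmissible) unless a positive ``floor`` is configured for noisy
    posteriors.
    """
    n = len(posteriors)
    if start < 1 or start + n - 1 > len(sequence):
        raise MappingError(
            f"start {start} puts a length-{n} chain outside the {len(sequence)}-residue sequence"
        )
    total = 0.0
    for i, post in enumerate(posteriors):
        p = max(_prob(post, sequence[start + i - 1]), floor)
        if p <= 0.0:
            return -math.inf
        total += math.log(p)
    return total


def rank_placements(
    chain: Chain,
    posteriors: Sequence[PosteriorLike],
    sequence: str,
    boundary_constraints: bool = False,
    occupied: Sequence[int] = (),
    floor: float = 0.0,
) -> list[Placement]:
    """Evaluate every admissible start and rank by log score.

    Constraints only filter: ``boundary_constraints`` requires a proline
    immediately outside a proline-flagged boundary (and the sequence end at
    a terminus-flagged one); ``occupied`` (1-based positions already
    assigned) forbids overlap.  Ties are broken by ascending start.
    ``norm_prob`` renormalizes exp(log_score) over admissible placements.
    """
    n = len(chain)
    if len(posteriors) != n:
        raise MappingError("one posterior per chain member required")
    if n > len(sequence):
        raise MappingError(
            f"chain {chain.name} (length {n}) is longer than the sequence ({len(sequence)})"
        )
    occupied_set = set(occupied)
    placements: list[Placement] = []
    for start in range(1, len(sequence) - n + 2):
        reason = ""
        if boundary_constraints:
            if chain.left_boundary == "proline" and not (
                start >= 2 and sequence[start - 2] == "P"
            ):
                reason = "left boundary requires a preceding proline"
            elif chain.left_boundary == "terminus" and start != 1:
                reason = "left boundary requires the N-terminus"
            elif chain.right_boundary == "proline" and not (
                start + n <= len(sequence) and sequence[start + n - 1] == "P"
            ):
                reason = "right boundary requires a following proline"
            elif chain.right_boundary == "terminus" and start + n - 1 != len(sequence):
                reason = "right boundary requires the C-terminus"
        if not reason and occupied_set.intersection(range(start, start + n)):
            reason = "overlaps an assigned position"
        if reason:
            continue
        score = score_placement(posteriors, sequence, start, floor=floor)
        if math.isinf(score):
            continue
        placements.append(Placement(chain.name, start, score))

    if placements:
        mx = max(p.log_score for p in placements)
        weights = [math.exp(p.log_score - mx) for p in placements]
        total = sum(weights)
        for p, w in zip(placements, weights):
            p.norm_prob = w / total
    placements.sort(key=lambda p: (-p.log_score, p.start))
    return placements


def assign_report(
    chains: Sequence[Chain],
    sequence: str,
    cache: SubsetModelCache,
    boundary_constraints: bool = True,
    occupied: Sequence[int] = (),
    top: int = 5,
    display_threshold: float = 0.10,
) -> dict:
    """Ranked chain placements plus per-system type recognitions.

    Returns a JSON-serializable dict with, per chain, the top ``top``
    placements with normalized probabilities, and per unknown spin system
    the ranked types whose posterior exceeds ``display_threshold``.
    Deterministic: identical inputs give identical output.
    """
    report: dict = {"chains": [], "systems": []}
    for chain in chains:
        posts = [posterior_auto(cache, s) for s in chain.systems]
        ranked = rank_placements(
            chain,
            posts,
            sequence,
            boundary_constraints=boundary_constraints,
            occupied=occupied,
        )
        report["chains"].append(
            {
                "name": chain.name,
                "length": len(chain),
                "placements": [
                    {
                        "start": p.start,
                        "log_score": p.log_score,
                        "probability": p.norm_prob,
                    }
                    for p in ranked[:top]
                ],
            }
        )
        for s, post in zip(chain.systems, posts):
            report["systems"].append(
                {
                    "id": s.id,
                    "chain": chain.name,
                    "subset": post.subset.name,
                    "recognitions": [
                        {"type": c, "probability": post.posteriors[c]}
                        for c in post.ranking
                        if post.posteriors[c] > display_threshold
                    ],
                }
            )
    return report


def report_frames(report: Mapping) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten an assign_report dict into (placements, recognitions) tables."""
    prow = [
        {"chain": c["name"], "rank": i + 1, **p}
        for c in report["chains"]
        for i, p in enumerate(c["placements"])
    ]
    srow = [
        {"id": s["id"], "chain": s["chain"], "rank": i + 1, **r}
        for s in report["systems"]
        for i, r in enumerate(s["recognitions"])
    ]
    return (
        pd.DataFrame(prow, columns=["chain", "rank", "start", "log_score", "probability"]),
        pd.DataFrame(srow, columns=["id", "chain", "rank", "type", "probability"]),
    )
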