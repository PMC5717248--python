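"""Crystal-similarity scoring and ranking of candidate bound poses.

The score compares a candidate complex to a reference (crystal) structure
through a fixed list of antigen-antibody residue pairs: for each pair the
minimum inter-residue distance r_pair is measured in the candidate, and

    score = sqrt( sum_pairs (r_pair - r_pair_crystal)^2 / N_pairs )

i.e. the root-mean-square deviation of the pair distances from their
crystal values, in nm.  Lower is more similar; a candidate whose pair
distances all match the crystal scores exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import CistrajError, SelectionError, ValidationError
from .geometry import min_residue_distance
from .model_io import Frame, ResiduePairList, Structure


@dataclass
class SimilarityResult:
    score: float                     # nm
    per_pair: dict                   # pair key -> (r_pair, r_crystal, sq_dev)
    n_pairs: int


def _frame_of(structure: Structure) -> Frame:
    return Frame(time=0.0, positions=structure.positions, box=structure.box)


def similarity_score(
    structure: Structure,
    frame: Frame | None,
    pairs: ResiduePairList,
    mode: str = "all-atom",
) -> SimilarityResult:
    """Crystal-similarity score of one frame (or of the structure itself).

    ``frame`` may be None to score the structure's own coordinates.
    Raises :class:`SelectionError` naming the pair whose residues cannot be
    resolved.
    """
    if frame is None:
        frame = _frame_of(structure)
    if pairs.n_pairs < 1:
        raise ValidationError("need at least one residue pair")
    per_pair = {}
    sq = 0.0
    for p in pairs.pairs:
        try:
            r = min_residue_distance(structure, frame, p.res_a, p.res_b, mode=mode)
        except SelectionError as exc:
            raise SelectionError(
                f"cannot resolve pair {p.res_a}-{p.res_b}: {exc}"
            ) from exc
        dev2 = (r - p.r_crystal) ** 2
        per_pair[(p.res_a, p.res_b)] = (r, p.r_crystal, dev2)
        sq += dev2
    return SimilarityResult(
        score=float(np.sqrt(sq / pairs.n_pairs)), per_pair=per_pair, n_pairs=pairs.n_pairs
    )


def rank_poses(
    candidates: Iterable,
    pairs: ResiduePairList,
    mode: str = "all-atom",
) -> pd.DataFrame:
    """Rank candidate structures by ascending similarity score.

    ``candidates`` is an iterable of :class:`Structure` or ``(id, Structure)``
    pairs; bare structures are labelled by their input position.  Candidates
    whose score cannot be computed are skipped with a warning.  Ties keep
    input order (stable sort).
    """
    rows = []
    for i, item in enumerate(candidates):
        cid, s = item if isinstance(item, tuple) else (i, item)
        try:
            res = similarity_score(s, None, pairs, mode=mode)
        except CistrajError as exc:
            warnings.warn(f"skipping candidate {cid!r}: {exc}")
            continue
        rows.append({"id": cid, "score": res.score, "n_pairs": res.n_pairs})
    if not rows:
        raise ValidationError("no candidate could be scored")
    df = pd.DataFrame(rows)
    return df.sort_values("score", kind="stable").reset_index(drop=True)
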