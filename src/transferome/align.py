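"""Exhaustive ungapped end-to-end alignment of read pairs to a transcriptome.

Every placement of each mate on every transcript, in both orientations, is
scored by Hamming distance; mates must land on the same transcript in
opposite orientations and their distances are summed. This mirrors
end-to-end (no soft-clip) alignment where mismatches, not indels, are the
operative quantity; distances above a cap are censored (reported as
unaligned), never as a fabricated finite value.

"Unique" means exactly one placement - (transcript, orientation
configuration, offset pair) - achieves the minimum summed distance; with
integer Hamming distances this is equivalent to the second-best placement
being strictly worse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .simulate import _encode, _COMPLEMENT

_BIG = np.iinfo(np.int32).max // 4


@dataclass(frozen=True)
class AlignmentSummary:
    """Best end-to-end placement of one read pair on one transcriptome.

    ``mismatches`` is None when the pair did not align under the cap
    (censored: the true distance is only known to exceed the cap).
    """

    read_id: str
    genome: str
    aligned: bool
    unique: bool
    mismatches: int | None
    gene: str | None


class TranscriptomeIndex:
    """Encoded transcriptome supporting vectorized sliding-window scans.

    Transcripts may have unequal lengths; shorter ones are padded with a
    sentinel that mismatches every base, and invalid window offsets are
    masked out.
    """

    def __init__(self, records: list[tuple[str, str]], genome: str):
        if not records:
            raise ConfigError(f"empty transcriptome for genome '{genome}'")
        self.genome = genome
        self.genes = [name for name, _ in records]
        self.lengths = np.array([len(seq) for _, seq in records])
        width = int(self.lengths.max())
        mat = np.full((len(records), width), 255, dtype=np.uint8)
        for i, (_, seq) in enumerate(records):
            mat[i, : len(seq)] = _encode(seq.upper())
        self.matrix = mat

    def mate_distances(self, mate: str) -> tuple[np.ndarray, np.ndarray]:
        """Hamming distance of one mate at every (transcript, offset).

        Returns (forward, reverse-complement) arrays of shape
        (n_transcripts, n_offsets); invalid offsets hold a large sentinel.
        """
        k = len(mate)
        width = self.matrix.shape[1]
        if k > width:
            n = len(self.genes)
            empty = np.full((n, 1), _BIG, dtype=np.int32)
            return empty, empty
        windows = np.lib.stride_tricks.sliding_window_view(self.matrix, k, axis=1)
        out = []
        for seq in (_encode(mate.upper()), _COMPLEMENT[_encode(mate.upper())][::-1]):
            d = (windows != seq).sum(axis=2, dtype=np.int32)
            invalid = np.arange(d.shape[1])[None, :] > (self.lengths[:, None] - k)
            d[invalid] = _BIG
            out.append(d)
        return out[0], out[1]


def align_end_to_end(
    read_pair: tuple[str, str, str],
    index: TranscriptomeIndex,
    mismatch_cap: int = 10,
) -> AlignmentSummary:
    """Align one read pair ``(read_id, mate1, mate2)`` exhaustively."""
    read_id, m1, m2 = read_pair
    return _align_pair(read_id, m1, m2, index, mismatch_cap)


def _align_pair(
    read_id: str, m1: str, m2: str, index: TranscriptomeIndex, cap: int
) -> AlignmentSummary:
    if cap < 0:
        raise ConfigError("mismatch_cap must be >= 0")
    d1f, d1r = index.mate_distances(m1)
    d2f, d2r = index.mate_distances(m2)

    best_total = _BIG
    best_count = 0
    best_gene = None
    # two orientation configurations: (m1 fwd, m2 rev) and (m1 rev, m2 fwd)
    for a, b in ((d1f, d2r), (d1r, d2f)):
        min_a = a.min(axis=1)
        min_b = b.min(axis=1)
        totals = min_a + min_b
        t_best = int(totals.min())
        if t_best > best_total:
            continue
        hits = np.flatnonzero(totals == t_best)
        count = int(
            sum(
                (a[i] == min_a[i]).sum() * (b[i] == min_b[i]).sum()
                for i in hits
            )
        )
        if t_best < best_total:
            best_total = t_best
            best_count = count
            best_gene = index.genes[hits[0]]
        else:
            best_count += count
            if index.genes[hits[0]] != best_gene:
                best_gene = min(best_gene, index.genes[hits[0]])

    if best_total > cap:
        return AlignmentSummary(read_id, index.genome, False, False, None, None)
    return AlignmentSummary(
        read_id,
        index.genome,
        True,
        best_count == 1,
        best_total,
        best_gene if best_count == 1 else best_gene,
    )


def align_sample(
    pairs: list[tuple[str, str, str]],
    index: TranscriptomeIndex,
    mismatch_cap: int = 10,
) -> pd.DataFrame:
    """Align many read pairs; returns the alignment-summary table."""
    rows = [align_end_to_end(p, index, mismatch_cap) for p in pairs]
    return summaries_to_frame(rows)


def summaries_to_frame(summaries: list[AlignmentSummary]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "read_id": [s.read_id for s in summaries],
            "genome": [s.genome for s in summaries],
            "aligned": [s.aligned for s in summaries],
            "unique": [s.unique for s in summaries],
            "mismatches": pd.array(
                [s.mismatches for s in summaries], dtype="Int64"
            ),
            "gene": [s.gene for s in summaries],
        }
    )
    return frame
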