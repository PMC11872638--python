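"""Position-weight-matrix scanning of promoter sequences.

A PWM stores per-position base preferences as (possibly fractional)
counts; with pseudocount c the position probabilities are
p = (count + c) / sum(count + c), and a window w of the same length scores

    S(w) = sum_pos log2( p_pos(w_pos) / bg(w_pos) )

against a background base distribution (uniform by default).  A gene is
called a motif target when its best window score — over both strands when
enabled — reaches ``threshold_fraction`` of the maximum achievable score
sum_pos max_base log2(p/bg).  Windows containing N (or any non-ACGT code)
are skipped rather than penalized, so ambiguity codes cannot create hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PWMError(ValueError):
    pass


@dataclass
class PWM:
    """A nucleotide motif model scored as log2 odds vs background."""

    motif_id: str
    name: str
    counts: np.ndarray  # shape (4, L), rows A,C,G,T, non-negative
    pseudocount: float = 0.01
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise PWMError(f"{self.motif_id}: counts must be 4 x L")
        if (self.counts < 0).any():
            raise PWMError(f"{self.motif_id}: negative counts")
        if not np.isclose(self.background.sum(), 1.0):
            raise PWMError(f"{self.motif_id}: background must sum to 1")
        if self.pseudocount < 0:
            raise PWMError(f"{self.motif_id}: negative pseudocount")

    def __len__(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        padded = self.counts + self.pseudocount
        return padded / padded.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=0))

    def score_window(self, window: str) -> float:
        """Log-odds score of one window; -inf if it contains non-ACGT."""
        if len(window) != len(self):
            raise ValueError("window length must equal motif length")
        lo = self.log_odds
        total = 0.0
        for pos, base in enumerate(window.upper()):
            i = _BASE_IDX.get(base)
            if i is None:
                return float("-inf")
            total += lo[i, pos]
        return total


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    enc = np.full(arr.shape, -1, dtype=np.int8)
    for base, i in _BASE_IDX.items():
        enc[arr == ord(base)] = i
    return enc


def best_score(pwm: PWM, seq: str, both_strands: bool = True) -> float:
    """Best window score of ``pwm`` along ``seq`` (-inf if no valid window)."""
    L = len(pwm)
    strands = [seq, reverse_complement(seq)] if both_strands else [seq]
    best = float("-inf")
    lo = pwm.log_odds
    for s in strands:
        if len(s) < L:
            continue
        enc = _encode(s)
        wins = np.lib.stride_tricks.sliding_window_view(enc, L)
        valid = (wins >= 0).all(axis=1)
        if not valid.any():
            continue
        idx = np.clip(wins[valid], 0, 3)
        scores = lo[idx, np.arange(L)].sum(axis=1)
        best = max(best, float(scores.max()))
    return best


# -- JASPAR-style I/O -------------------------------------------------------

def read_pwm_jaspar(path) -> list[PWM]:
    """Parse JASPAR-style motif text: ``>ID NAME`` then 4 base rows of counts.

    Both bracketed rows (``A [ 1 2 3 ]``) and bare whitespace-separated rows
    are accepted; rows may or may not carry a leading base letter, in which
    case A, C, G, T order is assumed.
    """
    text = Path(path).read_text()
    pwms: list[PWM] = []
    header = None
    rows: dict[str, list[float]] = {}
    order: list[str] = []

    def _flush():
        nonlocal header, rows, order
        if header is None:
            return
        if len(order) != 4:
            raise PWMError(f"motif {header[0]}: expected 4 base rows, got {len(order)}")
        lengths = {len(rows[b]) for b in order}
        if len(lengths) != 1:
            raise PWMError(f"motif {header[0]}: unequal row lengths {sorted(lengths)}")
        counts = np.array([rows[b] for b in BASES])
        pwms.append(PWM(motif_id=header[0], name=header[1], counts=counts))
        header, rows, order = None, {}, []

    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            parts = line[1:].split(None, 1)
            header = (parts[0], parts[1].strip() if len(parts) > 1 else parts[0])
            continue
        if header is None:
            raise PWMError(f"line {ln}: counts before any '>' header")
        toks = line.replace("[", " ").replace("]", " ").split()
        if toks and toks[0].upper() in _BASE_IDX and not _is_number(toks[0]):
            base, nums = toks[0].upper(), toks[1:]
        else:
            base, nums = BASES[len(order)], toks
        if base in rows:
            raise PWMError(f"line {ln}: duplicate row for base {base}")
        try:
            rows[base] = [float(t) for t in nums]
        except ValueError as exc:
            raise PWMError(f"line {ln}: malformed count row: {line!r}") from exc
        order.append(base)
    _flush()
    if not pwms:
        raise PWMError(f"no motifs found in {path}")
    return pwms


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_pwm_jaspar(pwms, path) -> None:
    lines = []
    for p in pwms:
        lines.append(f">{p.motif_id} {p.name}")
        for i, b in enumerate(BASES):
            nums = " ".join(f"{v:g}" for v in p.counts[i])
            lines.append(f"{b} [ {nums} ]")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in FASTA {path}")
    return seqs


def scan_promoters(
    pwms,
    promoters,
    threshold_fraction: float = 0.8,
    both_strands: bool = True,
    universe=None,
) -> "GeneSetAnnotation":
    """Call motif-target genes by thresholded best-window PWM score.

    ``promoters`` is a FASTA path or a gene -> sequence mapping.  Returns a
    :class:`~tomoseq.enrichment.GeneSetAnnotation` with one term per motif
    (term id = motif name) over the scanned genes (or ``universe`` if given).
    """
    from .enrichment import GeneSetAnnotation  # local import avoids a cycle

    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    if isinstance(pwms, PWM):
        pwms = [pwms]
    if not isinstance(promoters, dict):
        promoters = read_fasta(promoters)

    sets: dict[str, set] = {}
    for pwm in pwms:
        targets = set()
        for gene, seq in promoters.items():
            if len(seq) < len(pwm):
                warnings.warn(
                    f"promoter of {gene} shorter than motif {pwm.name}; skipped"
                )
                continue
            if best_score(pwm, seq, both_strands) >= threshold_fraction * pwm.max_score:
                targets.add(gene)
        sets[pwm.name] = targets
    uni = set(universe) if universe is not None else set(promoters)
    return GeneSetAnnotation(sets=sets, universe=uni)
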