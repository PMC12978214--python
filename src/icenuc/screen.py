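"""Sequence-level screening for ice-nucleating-protein signatures.

Protein level: detection of the 16-residue tandem repeats that build the
central repeating domain (CRD) of beta-solenoid INpros, arrays of the
ice-binding motifs (TxT, SLT, SxLT, TQT) and the dimerization motif YGS,
position-frequency (logo) matrices of repeat blocks, and the cysteine
capping architecture (six Cys near the C terminus, two at the CRD start).

DNA level: GC content and relative synonymous codon usage (RSCU) per gene,
the composition statistics used as horizontal-gene-transfer evidence.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_MOTIFS = {
    "TxT": "TxT",
    "SLT": "SLT",
    "SxLT": "SxLT",
    "TQT": "TQT",
    "YGS": "YGS",
}


@dataclass
class RepeatBlock:
    """A maximal run of tandem repeats with a fixed period."""

    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    period: int
    n_copies: int
    consensus: str
    mean_identity: float


@dataclass
class RepeatAnnotation:
    """Repeat blocks, motif sites, logo matrix and cysteine profile."""

    blocks: list = field(default_factory=list)
    motif_sites: list = field(default_factory=list)
    pfm: np.ndarray | None = None
    cys_positions: list = field(default_factory=list)


def _sliding_mean(x: np.ndarray, half: int) -> np.ndarray:
    """Centered moving average with windows truncated at the edges.

    Symmetric under sequence reversal, which keeps repeat calls
    mirror-consistent.
    """
    n = x.size
    cs = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def _majority(col) -> str:
    """Most frequent residue in a column, ties broken alphabetically."""
    counts: dict[str, int] = {}
    for c in col:
        counts[c] = counts.get(c, 0) + 1
    return max(sorted(counts), key=lambda c: counts[c])


def find_period_repeats(
    seq: str,
    period: int = 16,
    min_copies: int = 4,
    min_identity: float = 0.5,
) -> list[RepeatBlock]:
    """Detect tandem-repeat blocks by period-identity autocorrelation.

    Positions where residue i matches residue i+period, averaged over a
    centered window of about three periods, mark repeat-phase regions;
    maximal runs above ``min_identity`` become blocks (merged when their
    extents overlap).  Copy count is the floor of block length over the
    period; the consensus is majority-rule over full copies (ties broken
    alphabetically).
    """
    if not seq:
        raise ValueError("empty sequence")
    if period < 2:
        raise ValueError("period must be >= 2")
    seq = seq.upper()
    n = len(seq)
    if n < period + 1:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ind = (arr[:-period] == arr[period:]).astype(float)
    smooth = _sliding_mean(ind, half=(3 * period) // 2)
    mask = smooth >= min_identity
    # maximal runs of True
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    intervals = [(int(a), int(b) + period) for a, b in zip(edges[::2], edges[1::2])]
    # merge block extents that overlap after the +period extension
    merged: list[list[int]] = []
    for a, b in intervals:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    blocks = []
    for a, b in merged:
        n_copies = (b - a) // period
        if n_copies < min_copies:
            continue
        mean_id = float(ind[a : b - period].mean())
        copies = [seq[a + k * period : a + (k + 1) * period] for k in range(n_copies)]
        consensus = "".join(_majority(col) for col in zip(*copies))
        blocks.append(
            RepeatBlock(
                start=a,
                end=b,
                period=period,
                n_copies=n_copies,
                consensus=consensus,
                mean_identity=mean_id,
            )
        )
    return blocks


def motif_positions(seq: str, motifs: dict | None = None) -> list[tuple[str, int]]:
    """All (possibly overlapping) motif match positions, 0-based.

    Motifs use one-letter amino-acid codes with ``x`` matching any residue.
    """
    seq = seq.upper()
    motifs = DEFAULT_MOTIFS if motifs is None else motifs
    sites = []
    for name, pattern in motifs.items():
        pat = pattern.upper()
        if not pat or any(c not in AA_ALPHABET + "X" for c in pat):
            raise ValueError(f"malformed motif {pattern!r}")
        m = len(pat)
        for i in range(len(seq) - m + 1):
            if all(p == "X" or p == seq[i + j] for j, p in enumerate(pat)):
                sites.append((name, i))
    return sites


def repeat_logo(block: RepeatBlock, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Position-frequency matrix and information content of a repeat block.

    Returns a (period x 20) matrix of per-position residue frequencies
    across full copies (columns sum to 1, residue order ``AA_ALPHABET``)
    and the per-position information content log2(20) - entropy in bits.
    """
    if block.n_copies < 2:
        raise ValueError("need >= 2 copies for a logo")
    seq = seq.upper()
    idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    pfm = np.zeros((block.period, len(AA_ALPHABET)))
    for k in range(block.n_copies):
        copy = seq[block.start + k * block.period : block.start + (k + 1) * block.period]
        for j, aa in enumerate(copy):
            pfm[j, idx[aa]] += 1.0
    pfm /= pfm.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pfm > 0, pfm * np.log2(pfm), 0.0)
    info = np.log2(len(AA_ALPHABET)) + plogp.sum(axis=1)
    return pfm, info


def cys_profile(
    seq: str, terminal_window: float = 0.15
) -> tuple[int, int, int, list[int]]:
    """Cysteine counts overall and within the terminal windows.

    The window length is the floor of ``terminal_window`` times the sequence
    length; returns (n_total, n_cterm, n_nterm, positions).
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    positions = [i for i, aa in enumerate(seq) if aa == "C"]
    w = int(len(seq) * terminal_window)
    n_nterm = sum(1 for i in positions if i < w)
    n_cterm = sum(1 for i in positions if i >= len(seq) - w)
    return len(positions), n_cterm, n_nterm, positions


def gc_content(cds: str) -> float:
    """GC fraction of a coding sequence; N bases drop out of the denominator."""
    s = cds.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected nucleotides {sorted(bad)}")
    effective = len(s) - s.count("N")
    if effective == 0:
        raise ValueError("no unambiguous bases")
    return (s.count("G") + s.count("C")) / effective


def _standard_code() -> tuple[dict, dict]:
    table = unambiguous_dna_by_id[1]
    codon_to_aa = dict(table.forward_table)
    aa_to_codons: dict[str, list[str]] = {}
    for codon, aa in codon_to_aa.items():
        aa_to_codons.setdefault(aa, []).append(codon)
    return codon_to_aa, aa_to_codons


def rscu(cds: str) -> dict[str, float]:
    """Relative synonymous codon usage of a coding sequence.

    For codon c of an amino acid with k synonymous codons observed n_a times
    in total, RSCU_c = n_c / (n_a / k).  Codons of amino acids never
    observed are absent from the map; stop codons are excluded.  A terminal
    stop is trimmed; internal stops trigger a warning.
    """
    s = cds.upper().replace("U", "T")
    codon_to_aa, aa_to_codons = _standard_code()
    stops = {"TAA", "TAG", "TGA"}
    if len(s) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if codons and codons[-1] in stops:
        codons = codons[:-1]
    internal = [i for i, c in enumerate(codons) if c in stops]
    if internal:
        warnings.warn(f"internal stop codons at codon positions {internal}")
        codons = [c for c in codons if c not in stops]
    counts: dict[str, int] = {}
    for c in codons:
        if c not in codon_to_aa:
            raise ValueError(f"unrecognized codon {c!r}")
        counts[c] = counts.get(c, 0) + 1
    out: dict[str, float] = {}
    for aa, fam in aa_to_codons.items():
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            continue
        k = len(fam)
        for c in fam:
            out[c] = counts.get(c, 0) / (total / k)
    return out


@dataclass
class CodonStats:
    """Per-gene composition statistics for HGT screening."""

    gene_id: str
    gc: float
    rscu: dict[str, float]
    length_codons: int

    @classmethod
    def from_cds(cls, gene_id: str, cds: str) -> "CodonStats":
        return cls(
            gene_id=gene_id,
            gc=gc_content(cds),
            rscu=rscu(cds),
            length_codons=len(cds) // 3,
        )


def annotate(seq: str, period: int = 16, **repeat_kwargs) -> RepeatAnnotation:
    """Full protein-level annotation: repeats, motifs, logo, cysteines."""
    blocks = find_period_repeats(seq, period=period, **repeat_kwargs)
    sites = motif_positions(seq)
    pfm = None
    if blocks:
        longest = max(blocks, key=lambda b: b.n_copies)
        if longest.n_copies >= 2:
            pfm, _ = repeat_logo(longest, seq)
    _, _, _, cys = cys_profile(seq)
    return RepeatAnnotation(blocks=blocks, motif_sites=sites, pfm=pfm, cys_positions=cys)
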