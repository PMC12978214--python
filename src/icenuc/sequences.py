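"""Synthetic INpro-like sequence generator (synthetic stand-ins, not real genes).

Builds protein sequences with the architecture of fungal ice-nucleating
proteins — a flexible N-terminal linker, two cysteines at the start of a
central repeating domain (CRD) of 16-residue beta-solenoid coils carrying
TQT/SLT/YGS motifs, and a C-terminal region with six cysteines — plus
reverse-translated coding sequences with a controllable GC bias, emulating
the elevated GC content of horizontally transferred genes.  Used for tests
and demonstrations; no real INpro sequence is reproduced.
"""

from __future__ import annotations

import numpy as np

from .screen import AA_ALPHABET, _standard_code

#: 16-residue consensus coil used by the synthetic CRD: one beta-solenoid
#: coil with a TQT ice-binding array position, an SLT array and a YGS
#: dimerization motif.
CONSENSUS_COIL = "AGYGSTQTAGESSLTA"


def synthetic_inpro_protein(
    n_repeats: int = 31,
    linker_length: int = 120,
    cterm_length: int = 60,
    substitution_rate: float = 0.05,
    seed: int = 0,
) -> str:
    """A synthetic INpro-like protein with a noisy 16-residue CRD.

    The CRD consensus coil is repeated ``n_repeats`` times with random
    substitutions at ``substitution_rate``; two cysteines precede the CRD
    and six sit in the C-terminal region.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_ALPHABET.replace("C", "")))
    linker = "".join(rng.choice(letters, size=linker_length))
    crd = []
    for _ in range(n_repeats):
        coil = list(CONSENSUS_COIL)
        for j in range(len(coil)):
            if rng.random() < substitution_rate:
                coil[j] = str(rng.choice(letters))
        crd.append("".join(coil))
    cterm = list("".join(rng.choice(letters, size=cterm_length)))
    for pos in rng.choice(cterm_length - 1, size=6, replace=False):
        cterm[pos] = "C"
    return linker + "CC" + "".join(crd) + "".join(cterm)


def reverse_translate(
    protein: str, gc_bias: float = 0.5, seed: int = 0
) -> str:
    """Reverse-translate with codon choice weighted toward GC-rich codons.

    ``gc_bias`` in [0, 1] interpolates between preferring AT-rich and
    GC-rich synonymous codons, emulating donor-genome codon usage.
    """
    rng = np.random.default_rng(seed)
    _, aa_to_codons = _standard_code()
    out = []
    for aa in protein.upper():
        codons = sorted(aa_to_codons[aa])
        gc = np.array([c.count("G") + c.count("C") for c in codons], dtype=float)
        w = np.exp((2 * gc_bias - 1) * gc)
        out.append(str(rng.choice(codons, p=w / w.sum())))
    return "".join(out) + "TAA"


def write_fasta(path, records: dict[str, str]) -> None:
    """Write a {name: sequence} map as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into a {name: sequence} map (Biopython parser)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
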