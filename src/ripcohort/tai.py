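"""tRNA adaptation index (tAI) weights and per-gene codon-optimality scores.

Codon absolute adaptiveness is W_c = sum over pairings (1 - s) * tGCN, where
tGCN is the anticodon's tRNA gene copy number and s the wobble-pairing
penalty of the codon:anticodon class (Watson-Crick pairing has s = 0).  Each
sense codon is served by its Watson-Crick anticodon plus at most one wobble
anticodon within its codon box:

    codon ..U  <- anticodon G.. (G:U wobble)
    codon ..C  <- anticodon A.. (inosine, I:C)
    codon ..A  <- anticodon A.. (inosine, I:A)
    codon ..G  <- anticodon U.. (U:G wobble)

Relative weights are w_c = W_c / max(W); codons with no tRNA at all receive
the geometric mean of the nonzero weights.  The per-gene score ("classical
TE" here) is the geometric mean of w over the CDS codons, start and stop
excluded — each gene's own codon usage is how usage enters the score.

Default penalties follow the canonical published wobble values
(G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_COMP = str.maketrans("ACGT", "TGCA")
DEFAULT_S = {"WC": 0.0, "G:U": 0.41, "I:C": 0.28, "I:A": 0.9999, "U:G": 0.68}
_WOBBLE_CLASS = {"T": "G:U", "C": "I:C", "A": "I:A", "G": "U:G"}
# wobble anticodon = revcomp of the codon with its third base swapped so the
# anticodon's 5' (wobble) base becomes the reader above
_WOBBLE_THIRD = {"T": "C", "C": "T", "A": "T", "G": "A"}
STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def sense_codons() -> list[str]:
    bases = "TCAG"
    return [a + b + c for a in bases for b in bases for c in bases
            if a + b + c not in STOPS]


@dataclass
class TAIModel:
    """Fitted codon adaptiveness: absolute W, relative w, and inputs."""

    tGCN: pd.Series
    s: dict
    W: pd.Series
    w: pd.Series
    w_geo: float

    def weight(self, codon: str) -> float:
        return float(self.w.loc[codon])


def tai_weights(tGCN: pd.Series | dict, s_table: dict | None = None) -> TAIModel:
    """Compute codon tAI weights from anticodon gene copy numbers."""
    tGCN = pd.Series(tGCN, dtype=float)
    if (tGCN < 0).any():
        bad = list(tGCN.index[tGCN < 0])
        raise ValueError(f"negative tRNA gene copy number for anticodon(s) {bad}")
    s = dict(DEFAULT_S)
    if s_table:
        s.update(s_table)
    for cls, val in s.items():
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"penalty for class {cls!r} must lie in [0,1]")

    def copies(ac: str) -> float:
        return float(tGCN.get(ac, 0.0))

    W = {}
    for codon in sense_codons():
        wc_ac = revcomp(codon)
        w_val = (1.0 - s["WC"]) * copies(wc_ac)
        third = codon[2]
        wob_ac = revcomp(codon[:2] + _WOBBLE_THIRD[third])
        if wob_ac != wc_ac:
            w_val += (1.0 - s[_WOBBLE_CLASS[third]]) * copies(wob_ac)
        W[codon] = w_val
    W = pd.Series(W, name="W")
    if W.max() <= 0:
        raise ValueError("all codon adaptiveness values are zero; check tGCN")
    w = W / W.max()
    nz = w[w > 0]
    w_geo = float(np.exp(np.mean(np.log(nz))))
    w = w.where(w > 0, w_geo)
    w.name = "w"
    return TAIModel(tGCN=tGCN, s=s, W=W, w=w, w_geo=w_geo)


def gene_tai(cds_sequence: str, model: TAIModel) -> float:
    """Geometric mean of codon weights over a CDS (start/stop excluded)."""
    seq = cds_sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons[0] != "ATG":
        raise ValueError("CDS must begin with ATG")
    if codons[-1] not in STOPS:
        raise ValueError("CDS must end with a stop codon")
    for pos, c in enumerate(codons[1:-1], start=2):
        if c in STOPS:
            raise ValueError(f"internal stop codon {c} at codon position {pos}")
    scored = codons[1:-1]
    if not scored:
        raise ValueError("CDS has no codons to score between start and stop")
    logs = np.log([model.weight(c) for c in scored])
    return float(np.exp(np.mean(logs)))


def gene_te_table(cds_seqs: dict[str, str], model: TAIModel) -> pd.DataFrame:
    """Per-gene tAI table; ``classical_te`` is the tAI identification."""
    rows = {g: gene_tai(s, model) for g, s in cds_seqs.items()}
    tai = pd.Series(rows, name="tai")
    return pd.DataFrame({"tai": tai, "classical_te": tai})
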