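"""Cytosine-context classification and clone-level bisulfite tallies.

Plant methyltransferase pathways distinguish cytosine contexts CG, CHG
and CHH (H = A, C or T).  A forward-strand C at position i is CG when
the next base is G, CHG when base i+2 is G, else CHH; the reverse strand
is classified symmetrically on the reverse complement.  Cytosines too
close to the relevant end to see their context (or whose context window
contains N) are counted as cytosines but excluded from context tallies.

Bisulfite conversion turns unmethylated C to T (read on the sequenced
strand); a reference C read as C in a clone is methylated, read as T
unmethylated, anything else excluded.  Reverse-strand cytosines appear
as reference G read as G (methylated) or A (converted).  Percentages
are computed per clone and then averaged over the clone set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reads import revcomp

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class CytosineSite:
    pos: int          # 0-based position of the C on the forward reference
    strand: str       # '+' : base is C; '-' : base is G (C on the other strand)
    context: str | None  # None = unclassifiable (end rule or N)


@dataclass
class ContextTally:
    """Per-target methylation percentages, per context, averaged over clones."""

    n_clones: int
    cytosine_content_pct: float
    per_clone: pd.DataFrame            # clone x (context -> pct, overall)
    mean_pct: dict[str, float] = field(default_factory=dict)
    counts: dict[str, tuple[float, float]] = field(default_factory=dict)


def _context_at(seq: str, i: int) -> str | None:
    """Context of the forward-strand C at seq[i]; None if unclassifiable."""
    n = len(seq)
    if i + 1 >= n:
        return None
    b1 = seq[i + 1]
    if b1 == "G":
        return "CG"
    if b1 == "N":
        return None
    if i + 2 >= n:
        return None
    b2 = seq[i + 2]
    if b2 == "G":
        return "CHG"
    if b2 == "N":
        return None
    return "CHH"


def classify_contexts(sequence: str) -> list[CytosineSite]:
    """Every cytosine of both strands with its context (or None).

    Reverse-strand cytosines (forward-strand Gs) are classified on the
    reverse complement and reported at their forward coordinate.
    """
    seq = sequence.upper()
    sites: list[CytosineSite] = []
    for i, b in enumerate(seq):
        if b == "C":
            sites.append(CytosineSite(i, "+", _context_at(seq, i)))
    rc = revcomp(seq)
    n = len(seq)
    for j, b in enumerate(rc):
        if b == "C":
            sites.append(CytosineSite(n - 1 - j, "-", _context_at(rc, j)))
    return sites


def context_counts(sequence: str) -> dict[str, int]:
    """Classifiable-context totals over both strands plus the C tally."""
    sites = classify_contexts(sequence)
    out = {c: 0 for c in CONTEXTS}
    out["unclassifiable"] = 0
    for s in sites:
        if s.context is None:
            out["unclassifiable"] += 1
        else:
            out[s.context] += 1
    out["total_cytosines"] = len(sites)
    return out


def tally_clone_methylation(target_reference: str, clones: list[str],
                            ) -> ContextTally:
    """Methylation tally of aligned clone sequences against a target.

    Clones must equal the reference length (pre-aligned; gap columns may
    be '-' and are excluded at that clone).
    """
    ref = target_reference.upper()
    sites = classify_contexts(ref)
    per_clone_rows = []
    agg: dict[str, list[float]] = {c: [0.0, 0.0] for c in (*CONTEXTS, "overall")}
    for ci, clone in enumerate(clones):
        clone = clone.upper()
        if len(clone) != len(ref):
            raise ValueError(
                f"clone {ci}: length {len(clone)} != reference {len(ref)}")
        row = {}
        counts = {c: [0, 0] for c in (*CONTEXTS, "overall")}  # meth, total
        for site in sites:
            base = clone[site.pos]
            if site.strand == "+":
                meth = base == "C"
                unmeth = base == "T"
            else:
                meth = base == "G"
                unmeth = base == "A"
            if not (meth or unmeth):
                continue
            keys = ["overall"] + ([site.context] if site.context else [])
            for key in keys:
                counts[key][0] += int(meth)
                counts[key][1] += 1
        for key, (m, t) in counts.items():
            row[f"{key}_pct"] = 100.0 * m / t if t else np.nan
            agg[key][0] += m
            agg[key][1] += t
        per_clone_rows.append(row)

    per_clone = pd.DataFrame(per_clone_rows)
    mean_pct = {
        key: float(per_clone[f"{key}_pct"].mean())
        for key in (*CONTEXTS, "overall")
    }
    n_c = sum(1 for b in ref if b in "CG")
    return ContextTally(
        n_clones=len(clones),
        cytosine_content_pct=100.0 * n_c / len(ref) if ref else 0.0,
        per_clone=per_clone,
        mean_pct=mean_pct,
        counts={k: (v[0], v[1]) for k, v in agg.items()},
    )


def align_clone(reference: str, clone: str) -> str:
    """End-gap-free placement of a (possibly shorter) clone on the reference.

    Slides the clone over the reference scoring matches, with C->T (and
    G->A) conversions scored as matches, and pads with '-' so the result
    has the reference length.  A convenience for unaligned input; real
    multiple alignment is out of scope.
    """
    ref, clone = reference.upper(), clone.upper()
    if len(clone) > len(ref):
        raise ValueError("clone longer than reference")
    best, best_off = -1, 0
    for off in range(len(ref) - len(clone) + 1):
        score = 0
        for r, c in zip(ref[off:off + len(clone)], clone):
            if r == c or (r == "C" and c == "T") or (r == "G" and c == "A"):
                score += 1
        if score > best:
            best, best_off = score, off
    return "-" * best_off + clone + "-" * (len(ref) - len(clone) - best_off)


def validate_against_rpkm(percent_methylated, window_rpkm, window_maxdepth,
                          ) -> dict:
    """OLS R^2 of %-methylated against RPKM and max per-bp coverage."""
    y = np.asarray(percent_methylated, dtype=float)
    if y.size < 3:
        raise ValueError("need >= 3 targets")
    out = {}
    for name, x in (("r2_rpkm", window_rpkm), ("r2_maxdepth", window_maxdepth)):
        x = np.asarray(x, dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out[name] = None
            continue
        res = np.polyfit(x, y, 1)
        pred = np.polyval(res, x)
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        out[name] = 1.0 - ss_res / ss_tot
    return out
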