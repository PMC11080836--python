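"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: the adapter oracles
enumerate candidate alignments explicitly and score them with edlib, the
quality-trim oracle evaluates every cut position by its definition, and the
log-CPM oracle re-states the closed form per element.
"""

from __future__ import annotations

import math

import edlib
import numpy as np

from dimerqc.adapters import AdapterMode, AdapterSpec

_TIEKEY = lambda m: (lambda t: (t[0], m - t[1], t[2], t[3]))  # noqa: E731


def _budget(i: int, rate: float) -> int:
    return math.floor(rate * i + 1e-9)


def oracle_find_adapter_brute(bases: str, spec: AdapterSpec):
    """Exhaustive enumeration over every (start, end) read span and every
    admissible adapter span, each scored by a global edit-distance call.

    Returns (errors, aligned, start, end) of the best admissible candidate
    under the (fewest errors, most adapter bases, smallest start, smallest
    end) order, or None.
    """
    ad, m, n = spec.sequence, len(spec.sequence), len(bases)
    lo = spec.min_overlap
    cands = []
    for s in range(n):
        for e in range(s + 1, n + 1):
            d = edlib.align(ad, bases[s:e], mode="NW")["editDistance"]
            if d <= _budget(m, spec.error_rate):
                cands.append((d, m, s, e))
    if spec.mode in (AdapterMode.BACK, AdapterMode.ANYWHERE):
        for i in range(lo, m):
            for s in range(n):
                d = edlib.align(ad[:i], bases[s:n], mode="NW")["editDistance"]
                if d <= _budget(i, spec.error_rate):
                    cands.append((d, i, s, n))
    if spec.mode in (AdapterMode.FRONT, AdapterMode.ANYWHERE):
        for i in range(lo, m):
            for e in range(1, n + 1):
                d = edlib.align(ad[-i:], bases[:e], mode="NW")["editDistance"]
                if d <= _budget(i, spec.error_rate):
                    cands.append((d, i, 0, e))
    if not cands:
        return None
    return min(cands, key=_TIEKEY(m))


def oracle_find_adapter(bases: str, spec: AdapterSpec):
    """Faster exhaustive oracle: one semi-global edlib call per alignment
    start (full-adapter candidates) or per truncation length (read-end /
    read-start overhang candidates).  Same candidate optimum as the brute
    enumeration — edlib's prefix mode minimizes over all span ends for a
    fixed start — with dominated candidates (same span, more errors)
    dropped, which cannot change the winner under the tie-break order.
    """
    ad, m, n = spec.sequence, len(spec.sequence), len(bases)
    lo = spec.min_overlap
    rate = spec.error_rate
    cands = []
    for s in range(n):
        r = edlib.align(ad, bases[s:], mode="SHW", task="locations")
        d = r["editDistance"]
        if d <= _budget(m, rate):
            end = s + min(e for _, e in r["locations"]) + 1
            cands.append((d, m, s, end))
    if spec.mode in (AdapterMode.BACK, AdapterMode.ANYWHERE):
        rev = bases[::-1]
        for i in range(lo, m):
            r = edlib.align(ad[:i][::-1], rev, mode="SHW", task="locations")
            d = r["editDistance"]
            if d <= _budget(i, rate):
                span = max(e for _, e in r["locations"]) + 1
                if span > 0:
                    cands.append((d, i, n - span, n))
    if spec.mode in (AdapterMode.FRONT, AdapterMode.ANYWHERE):
        for i in range(lo, m):
            r = edlib.align(ad[-i:], bases, mode="SHW", task="locations")
            d = r["editDistance"]
            if d <= _budget(i, rate):
                end = min(e for _, e in r["locations"]) + 1
                if end > 0:
                    cands.append((d, i, 0, end))
    if not cands:
        return None
    return min(cands, key=_TIEKEY(m))


def oracle_trim_cut(quals, threshold: int) -> int:
    """Brute-force 3' quality-trim cut point: evaluate the partial sum
    ``S(i) = sum_{j>=i} (q_j - threshold)`` at every cut position and take
    the argmin, keeping the most bases on ties."""
    n = len(quals)
    best_cut, best_val = n, 0
    for i in range(n + 1):
        val = sum(q - threshold for q in quals[i:])
        if val < best_val or (val == best_val and i > best_cut):
            best_val, best_cut = val, i
    return best_cut


def oracle_log_cpm(counts: np.ndarray, prior: float) -> np.ndarray:
    """Element-wise closed-form log2-CPM recomputation."""
    out = np.empty(counts.shape, dtype=float)
    lib = counts.sum(axis=0)
    for f in range(counts.shape[0]):
        for s in range(counts.shape[1]):
            out[f, s] = math.log2(
                (counts[f, s] + prior) / (lib[s] + 2 * prior) * 1e6
            )
    return out


def random_triple(rng: np.random.Generator, specs, max_len: int = 100):
    """One randomized (read, adapter-spec) pair, sometimes with the adapter
    embedded carrying a few edits, for matcher equivalence testing."""
    spec = specs[int(rng.integers(len(specs)))]
    n = int(rng.integers(8, max_len + 1))
    bases = "".join(
        rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=n)
    )
    if rng.random() < 0.5:
        pos = int(rng.integers(0, max(1, n - 5)))
        frag = list(spec.sequence[: min(len(spec.sequence), n - pos)])
        for _ in range(int(rng.integers(0, 4))):
            if not frag:
                break
            op = rng.random()
            k = int(rng.integers(0, len(frag)))
            if op < 0.6:
                frag[k] = str(rng.choice(list("ACGT")))
            elif op < 0.8:
                del frag[k]
            else:
                frag.insert(k, str(rng.choice(list("ACGT"))))
        ins = "".join(frag)[: n - pos]
        bases = bases[:pos] + ins + bases[pos + len(ins):]
    return bases, spec
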