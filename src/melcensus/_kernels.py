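"""Numba dynamic-programming kernels.

Three aligners power the pipeline:

* :func:`sw_affine` — local (Smith-Waterman) protein alignment with affine
  gaps, used to extend translated-search seeds.
* :func:`nw_affine_matrix` — global (Needleman-Wunsch) alignment over an
  arbitrary pre-computed column-score matrix, used for pairwise protein
  alignment and profile-profile steps of the progressive MSA.
* :func:`spliced_sw` — local protein-to-genome alignment with an intron
  state (GT..AG, phase 0) and 1-2 bp frameshift transitions at codon
  boundaries, used for gene-structure reconstruction.

Gap convention throughout: a gap of length L costs ``go + (L-1)*ge`` where
``go`` is the cost of the first gap column (i.e. BLAST open 11 / extend 1
corresponds to ``go=12, ge=1``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**8))


@njit(cache=True)
def sw_affine(q, t, S, go, ge):  # pragma: no cover - exercised via wrappers
    """Local affine-gap alignment of index-encoded proteins.

    Returns ``(score, npath, pi, pj)`` where ``pi``/``pj`` hold, in
    alignment order, the 0-based residue index of each column (-1 = gap).
    """
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    pH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i - 1, j] - go
            e_ext = E[i - 1, j] - ge
            if e_open >= e_ext:
                E[i, j] = e_open
                pE[i, j] = 1
            else:
                E[i, j] = e_ext
                pE[i, j] = 2
            f_open = H[i, j - 1] - go
            f_ext = F[i, j - 1] - ge
            if f_open >= f_ext:
                F[i, j] = f_open
                pF[i, j] = 1
            else:
                F[i, j] = f_ext
                pF[i, j] = 2
            diag = H[i - 1, j - 1] + S[qi, t[j - 1]]
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            pH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    cap = n + m + 2
    pi = np.empty(cap, dtype=np.int32)
    pj = np.empty(cap, dtype=np.int32)
    k = 0
    i, j = bi, bj
    state = 0  # 0=H 1=E 2=F
    while True:
        if state == 0:
            p = pH[i, j]
            if p == 0:
                break
            if p == 1:
                pi[k] = i - 1
                pj[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            p = pE[i, j]
            pi[k] = i - 1
            pj[k] = -1
            k += 1
            i -= 1
            state = 0 if p == 1 else 1
        else:
            p = pF[i, j]
            pi[k] = -1
            pj[k] = j - 1
            k += 1
            j -= 1
            state = 0 if p == 1 else 2
    # reverse in place
    for a in range(k // 2):
        b = k - 1 - a
        pi[a], pi[b] = pi[b], pi[a]
        pj[a], pj[b] = pj[b], pj[a]
    return best, k, pi, pj


@njit(cache=True)
def nw_affine_matrix(Smat, go, ge):  # pragma: no cover - exercised via wrappers
    """Global affine-gap alignment over a column score matrix (end gaps penalised)."""
    n, m = Smat.shape
    H = np.full((n + 1, m + 1), -np.inf)
    E = np.full((n + 1, m + 1), -np.inf)  # gap in columns (consumes rows/i)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in rows (consumes cols/j)
    pH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        E[i, 0] = -(go + (i - 1) * ge)
        H[i, 0] = E[i, 0]
        pH[i, 0] = 2
        pE[i, 0] = 1 if i == 1 else 2
    for j in range(1, m + 1):
        F[0, j] = -(go + (j - 1) * ge)
        H[0, j] = F[0, j]
        pH[0, j] = 3
        pF[0, j] = 1 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i - 1, j] - go
            e_ext = E[i - 1, j] - ge
            if e_open >= e_ext:
                E[i, j] = e_open
                pE[i, j] = 1
            else:
                E[i, j] = e_ext
                pE[i, j] = 2
            f_open = H[i, j - 1] - go
            f_ext = F[i, j - 1] - ge
            if f_open >= f_ext:
                F[i, j] = f_open
                pF[i, j] = 1
            else:
                F[i, j] = f_ext
                pF[i, j] = 2
            diag = H[i - 1, j - 1] + Smat[i - 1, j - 1]
            h = diag
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            pH[i, j] = p
    cap = n + m + 2
    pi = np.empty(cap, dtype=np.int32)
    pj = np.empty(cap, dtype=np.int32)
    k = 0
    i, j = n, m
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = pH[i, j]
            if p == 1:
                pi[k] = i - 1
                pj[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            p = pE[i, j]
            pi[k] = i - 1
            pj[k] = -1
            k += 1
            i -= 1
            state = 0 if p == 1 else 1
        else:
            p = pF[i, j]
            pi[k] = -1
            pj[k] = j - 1
            k += 1
            j -= 1
            state = 0 if p == 1 else 2
    for a in range(k // 2):
        b = k - 1 - a
        pi[a], pi[b] = pi[b], pi[a]
        pj[a], pj[b] = pj[b], pj[a]
    return H[n, m], k, pi, pj


@njit(cache=True)
def sw_affine_banded(q, t, S, go, ge, dlo, dhi):  # pragma: no cover - via wrappers
    """Banded local affine-gap alignment: cells with j-i outside [dlo, dhi]
    are treated as empty (score 0), confining alignments to the seed band."""
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    pH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        j0 = max(1, i + dlo)
        j1 = min(m, i + dhi)
        for j in range(j0, j1 + 1):
            e_open = H[i - 1, j] - go
            e_ext = E[i - 1, j] - ge
            if e_open >= e_ext:
                E[i, j] = e_open
                pE[i, j] = 1
            else:
                E[i, j] = e_ext
                pE[i, j] = 2
            f_open = H[i, j - 1] - go
            f_ext = F[i, j - 1] - ge
            if f_open >= f_ext:
                F[i, j] = f_open
                pF[i, j] = 1
            else:
                F[i, j] = f_ext
                pF[i, j] = 2
            diag = H[i - 1, j - 1] + S[qi, t[j - 1]]
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            pH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    cap = n + m + 2
    pi = np.empty(cap, dtype=np.int32)
    pj = np.empty(cap, dtype=np.int32)
    k = 0
    i, j = bi, bj
    state = 0
    while True:
        if state == 0:
            p = pH[i, j]
            if p == 0:
                break
            if p == 1:
                pi[k] = i - 1
                pj[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            p = pE[i, j]
            pi[k] = i - 1
            pj[k] = -1
            k += 1
            i -= 1
            state = 0 if p == 1 else 1
        else:
            p = pF[i, j]
            pi[k] = -1
            pj[k] = j - 1
            k += 1
            j -= 1
            state = 0 if p == 1 else 2
    for a in range(k // 2):
        b = k - 1 - a
        pi[a], pi[b] = pi[b], pi[a]
        pj[a], pj[b] = pj[b], pj[a]
    return best, k, pi, pj


# Event codes emitted by spliced_sw tracebacks.
EV_MATCH = 0  # query residue aligned to the codon ending at j (delta in ev_k)
EV_QGAP = 1  # unaligned query residue (gap in DNA)
EV_TGAP = 2  # unaligned codon (gap in query)
EV_INTRON = 3  # intron from donor ev_k to acceptor ev_j


@njit(cache=True)
def spliced_sw(q, aa_at, donor, acceptor, S, go, ge, intron_open, fs_pen, min_intron):  # pragma: no cover
    """Local spliced protein-to-DNA alignment.

    ``aa_at[j]`` is the encoded amino acid of the codon occupying
    ``dna[j-3:j]`` (or -1 if ``j < 3``); ``donor[j]`` marks a GT starting at
    ``j``; ``acceptor[j]`` marks an AG ending at ``j``.  Codon-boundary
    transitions may slip by +-1/+-2 bp at ``fs_pen`` to model frameshifts.
    Returns ``(score, nev, ev_type, ev_i, ev_j, ev_k)`` with the traceback
    events in reverse (end-to-start) order.
    """
    n = len(q)
    m = len(aa_at) - 1
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    I = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    pM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    dM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pIdon = np.full((n + 1, m + 1), -1, dtype=np.int32)
    Dmax = np.full(n + 1, NEG, dtype=np.int64)
    Darg = np.full(n + 1, -1, dtype=np.int32)
    deltas = np.array([3, 2, 4, 1, 5], dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for j in range(m + 1):
        jd = j - min_intron
        if jd >= 0 and donor[jd]:
            for i in range(n + 1):
                v = M[i, jd]
                if v > Dmax[i]:
                    Dmax[i] = v
                    Darg[i] = jd
        if acceptor[j]:
            for i in range(n + 1):
                if Darg[i] >= 0:
                    v = Dmax[i] - intron_open
                    if v > I[i, j]:
                        I[i, j] = np.int32(v)
                        pIdon[i, j] = Darg[i]
        for i in range(1, n + 1):
            # Y: unmatched codon (gap in query)
            if j >= 3:
                y_open = M[i, j - 3] - go
                y_ext = Y[i, j - 3] - ge
                if y_open >= y_ext:
                    Y[i, j] = y_open
                    pY[i, j] = 1
                else:
                    Y[i, j] = y_ext
                    pY[i, j] = 2
            # X: unmatched query residue (gap in DNA)
            x_open = M[i - 1, j] - go
            x_ext = X[i - 1, j] - ge
            if x_open >= x_ext:
                X[i, j] = x_open
                pX[i, j] = 1
            else:
                X[i, j] = x_ext
                pX[i, j] = 2
            # M: query residue i-1 matched to the codon ending at j
            aa = aa_at[j]
            if aa >= 0:
                s = np.int32(S[q[i - 1], aa])
                bv = np.int32(0)  # fresh local start (delta 3 only)
                bp = np.uint8(0)
                bd = np.uint8(3)
                for di in range(5):
                    d = deltas[di]
                    jp = j - d
                    if jp < 0:
                        continue
                    pen = np.int32(0) if d == 3 else np.int32(fs_pen)
                    v = M[i - 1, jp] - pen
                    p = np.uint8(1)
                    if X[i - 1, jp] - pen > v:
                        v = X[i - 1, jp] - pen
                        p = np.uint8(2)
                    if Y[i - 1, jp] - pen > v:
                        v = Y[i - 1, jp] - pen
                        p = np.uint8(3)
                    if I[i - 1, jp] - pen > v:
                        v = I[i - 1, jp] - pen
                        p = np.uint8(4)
                    if v > bv:
                        bv = v
                        bp = p
                        bd = np.uint8(d)
                M[i, j] = s + bv
                pM[i, j] = bp
                dM[i, j] = bd
                if M[i, j] > best:
                    best = M[i, j]
                    bi = i
                    bj = j
    # traceback
    cap = n + m + 16
    ev_type = np.empty(cap, dtype=np.int8)
    ev_i = np.empty(cap, dtype=np.int32)
    ev_j = np.empty(cap, dtype=np.int32)
    ev_k = np.empty(cap, dtype=np.int32)
    k = 0
    i, j = bi, bj
    state = 0  # 0=M 1=X 2=Y 3=I
    if best <= 0:
        return 0, 0, ev_type, ev_i, ev_j, ev_k
    while True:
        if state == 0:
            d = dM[i, j]
            p = pM[i, j]
            ev_type[k] = EV_MATCH
            ev_i[k] = i - 1
            ev_j[k] = j
            ev_k[k] = d
            k += 1
            i -= 1
            j -= d
            if p == 0:
                break
            elif p == 1:
                state = 0
            elif p == 2:
                state = 1
            elif p == 3:
                state = 2
            else:
                state = 3
        elif state == 1:
            p = pX[i, j]
            ev_type[k] = EV_QGAP
            ev_i[k] = i - 1
            ev_j[k] = j
            ev_k[k] = 0
            k += 1
            i -= 1
            state = 0 if p == 1 else 1
        elif state == 2:
            p = pY[i, j]
            ev_type[k] = EV_TGAP
            ev_i[k] = i
            ev_j[k] = j
            ev_k[k] = 3
            k += 1
            j -= 3
            state = 0 if p == 1 else 2
        else:
            don = pIdon[i, j]
            ev_type[k] = EV_INTRON
            ev_i[k] = i
            ev_j[k] = j
            ev_k[k] = don
            k += 1
            j = don
            state = 0
    return best, k, ev_type, ev_i, ev_j, ev_k
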