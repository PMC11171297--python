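"""Mechanical spin summation: spin-orbital -> closed-shell spatial terms.

For a singlet state the doubles equations are fully determined by the
mixed-spin projection <Phi_{i-alpha j-beta}^{a-alpha b-beta}| and the singles
by <Phi_{i-alpha}^{a-alpha}|.  Each spin-orbital term is expanded over the
internal spin sums, the antisymmetrized integrals are split into chemists'
notation (pq|rs) pieces

    <pq||rs> = (pr|qs) d(sp,sr) d(sq,ss) - (ps|qr) d(sp,ss) d(sq,sr)

and the singlet amplitude blocks are reduced to the spatial tensors
t1[i,a], t2[i,j,a,b] (with t2[i,j,a,b] = t2[j,i,b,a]).  Equivalent terms are
merged using the permutational symmetries of (pq|rs), t2 and f.  The result
is generated once at import; nothing is transcribed by hand.
"""

from __future__ import annotations

import itertools

from .engine import OCC_LETTERS
from . import so_terms

_OCC_POOL = "ijklmn"
_VIRT_POOL = "abcdeg"


def _expand_term(coef, out, factors, out_spins):
    """Yield (coef, spatial_factors) pieces of one spin-orbital term."""
    letters = set("".join(s for _, s in factors)) | set(out)
    internal = sorted(letters - set(out))
    free_spin = dict(zip(out, out_spins))
    for combo in itertools.product((0, 1), repeat=len(internal)):
        spin = dict(free_spin)
        spin.update(zip(internal, combo))
        # expand each factor into its chemists'-notation branches
        branch_lists = []
        ok = True
        for name, subs in factors:
            branches = []
            if name in ("f", "t1"):
                if spin[subs[0]] == spin[subs[1]]:
                    branches.append((1.0, name, subs))
            elif name == "v":
                p, q, r, s = subs
                if spin[p] == spin[r] and spin[q] == spin[s]:
                    branches.append((1.0, "w", p + r + q + s))
                if spin[p] == spin[s] and spin[q] == spin[r]:
                    branches.append((-1.0, "w", p + s + q + r))
            elif name == "t2":
                p, q, r, s = subs
                if spin[p] == spin[r] and spin[q] == spin[s]:
                    branches.append((1.0, "t2", subs))
                if spin[p] == spin[s] and spin[q] == spin[r]:
                    branches.append((-1.0, "t2", p + q + s + r))
            else:  # pragma: no cover
                raise ValueError(name)
            if not branches:
                ok = False
                break
            branch_lists.append(branches)
        if not ok:
            continue
        for picks in itertools.product(*branch_lists):
            c = coef
            fs = []
            for sgn, nm, sb in picks:
                c *= sgn
                fs.append((nm, sb))
            yield c, tuple(fs)


def _variants(factors):
    """All symmetry-equivalent rewritings of a factor tuple."""
    per_factor = []
    for name, subs in factors:
        alts = {(name, subs)}
        if name == "w":
            p, q, r, s = subs
            for a, b in ((p, q), (q, p)):
                for c, d in ((r, s), (s, r)):
                    alts.add(("w", a + b + c + d))
                    alts.add(("w", c + d + a + b))
        elif name == "t2":
            p, q, r, s = subs
            alts.add(("t2", q + p + s + r))
        elif name == "f":
            alts.add(("f", subs[::-1]))
        per_factor.append(sorted(alts))
    for picks in itertools.product(*per_factor):
        for order in itertools.permutations(picks):
            yield order


def _canonical(out, factors):
    """Canonical key: minimal (renamed factors) over symmetry variants."""
    best = None
    for variant in _variants(factors):
        mapping = {c: c for c in out}
        occ_pool = [c for c in _OCC_POOL if c not in out]
        virt_pool = [c for c in _VIRT_POOL if c not in out]
        oi = vi = 0
        ok = True
        renamed = []
        for name, subs in variant:
            new = []
            for ch in subs:
                if ch not in mapping:
                    if ch in OCC_LETTERS:
                        mapping[ch] = occ_pool[oi]
                        oi += 1
                    else:
                        mapping[ch] = virt_pool[vi]
                        vi += 1
                new.append(mapping[ch])
            renamed.append((name, "".join(new)))
        key = tuple(renamed)
        if best is None or key < best:
            best = key
    return best


def spatial_terms(so_term_list, out, out_spins):
    """Spin-sum a spin-orbital term list into merged spatial terms."""
    merged = {}
    for coef, _, factors in so_term_list:
        for c, fs in _expand_term(coef, out, factors, out_spins):
            key = _canonical(out, fs)
            merged[key] = merged.get(key, 0.0) + c
    return [(c, out, list(k)) for k, c in merged.items() if abs(c) > 1e-12]


# Doubles: mixed-spin projection (alpha, beta, alpha, beta); singles: alpha.
R2_TERMS = spatial_terms(so_terms.doubles_terms(), "ijab", (0, 1, 0, 1))
R1_TERMS = spatial_terms(so_terms.singles_terms(), "ia", (0, 0))
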