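"""A minimal tensor-term engine for the linearized CC equations.

A *term* is ``(coef, out_subscript, ((name, subscript), ...))`` and denotes

    coef * einsum('s1,s2,...->out', T[name1,s1], T[name2,s2], ...)

Index letters encode orbital spaces: i j k l m n -> occupied, a b c d e g ->
virtual.  Tensor names: ``f`` (one-electron/Fock, sliced by block), ``v``
(antisymmetrized spin-orbital <pq||rs>), ``w`` (spatial chemists' (pq|rs),
sliced by block), ``t1``/``t2`` (amplitude slots).

Because every term is multilinear in its factors, three mechanical
operations give everything the linearized theory needs:

* ``evaluate``          -- the residual itself,
* ``jacobian_action``   -- d(residual)/d(amplitude) . delta, by replacing one
                           amplitude slot at a time,
* ``transpose_action``  -- the adjoint map for the Lambda equations, by
                           exchanging the output subscript with one slot,
* ``f_gradient``        -- d(lambda . residual)/d f, the one-electron
                           response density contribution, by exchanging the
                           output subscript with the f slot.

No equation is ever transcribed twice: the Lambda equations and response
densities are the mechanical transposes of the amplitude equations.
"""

from __future__ import annotations

import numpy as np

OCC_LETTERS = set("ijklmn")
VIRT_LETTERS = set("abcdeg")


def letter_class(letter: str) -> str:
    if letter in OCC_LETTERS:
        return "o"
    if letter in VIRT_LETTERS:
        return "v"
    raise ValueError(f"unknown index letter {letter!r}")


class TensorStore:
    """Resolves (name, subscript) -> ndarray.

    ``full``   : dict name -> full-space array, sliced by letter classes.
    ``blocked``: dict name -> callable(class_tuple) -> block array.
    ``plain``  : dict name -> array used as-is (amplitudes).
    """

    def __init__(self, n_occ, n_virt, full=None, blocked=None, plain=None):
        self.o = np.arange(n_occ)
        self.v = np.arange(n_occ, n_occ + n_virt)
        self.full = full or {}
        self.blocked = blocked or {}
        self.plain = dict(plain or {})
        self._cache = {}

    def set_plain(self, name, arr):
        self.plain[name] = arr

    def get(self, name, subs):
        if name in self.plain:
            return self.plain[name]
        key = (name, "".join(letter_class(c) for c in subs))
        if key in self._cache:
            return self._cache[key]
        classes = key[1]
        if name in self.full:
            arr = self.full[name]
            for axis, cls in enumerate(classes):
                idx = self.o if cls == "o" else self.v
                arr = np.take(arr, idx, axis=axis)
        else:
            arr = self.blocked[name](classes)
        self._cache[key] = arr
        return arr


_PATHS = {}


def _einsum(spec, *arrays):
    key = (spec, tuple(a.shape for a in arrays))
    path = _PATHS.get(key)
    if path is None:
        path = np.einsum_path(spec, *arrays, optimize="optimal")[0]
        _PATHS[key] = path
    return np.einsum(spec, *arrays, optimize=path)


def evaluate(terms, store: TensorStore, out_shape):
    total = np.zeros(out_shape)
    for coef, out, factors in terms:
        arrays = [store.get(n, s) for n, s in factors]
        spec = ",".join(s for _, s in factors) + "->" + out
        total += coef * _einsum(spec, *arrays)
    return total


def jacobian_action(terms, store: TensorStore, deltas: dict, out_shape):
    """Directional derivative w.r.t. the amplitude tensors named in
    ``deltas`` (e.g. {'t1': d1, 't2': d2}), at the base amplitudes held in
    the store.  Exact for multilinear terms."""
    total = np.zeros(out_shape)
    for coef, out, factors in terms:
        for k, (name, _) in enumerate(factors):
            if name not in deltas:
                continue
            arrays = []
            skip = False
            for m, (n2, s2) in enumerate(factors):
                if m == k:
                    arrays.append(deltas[name])
                else:
                    a = store.get(n2, s2)
                    arrays.append(a)
            spec = ",".join(s for _, s in factors) + "->" + out
            total += coef * _einsum(spec, *arrays)
    return total


def transpose_action(terms, store: TensorStore, lam, slot_name, slot_shape):
    """sum_mu lam_mu d(residual_mu)/d(amplitude ``slot_name``) -- the adjoint
    of ``jacobian_action`` contracted against lam (indexed by ``out``)."""
    total = np.zeros(slot_shape)
    for coef, out, factors in terms:
        for k, (name, subs) in enumerate(factors):
            if name != slot_name:
                continue
            others = [(n2, s2) for m, (n2, s2) in enumerate(factors) if m != k]
            arrays = [store.get(n2, s2) for n2, s2 in others] + [lam]
            spec = (",".join(s for _, s in others)
                    + ("," if others else "") + out + "->" + subs)
            total += coef * _einsum(spec, *arrays)
    return total


def f_gradient_linearized(terms, store: TensorStore, lam, primes: dict,
                          n_occ, n_virt):
    """d(lam . J t')/d f where J t' is the Jacobian action: every term with
    an f factor and one amplitude slot replaced by its prime tensor."""
    n = n_occ + n_virt
    grad = np.zeros((n, n))
    for coef, out, factors in terms:
        fslots = [k for k, (nm, _) in enumerate(factors) if nm == "f"]
        if not fslots:
            continue
        kf = fslots[0]
        fsubs = factors[kf][1]
        for k, (name, _) in enumerate(factors):
            if name not in primes:
                continue
            others = []
            arrays = []
            for m, (n2, s2) in enumerate(factors):
                if m == kf:
                    continue
                others.append(s2)
                arrays.append(primes[name] if m == k else store.get(n2, s2))
            arrays.append(lam)
            spec = (",".join(others) + ("," if others else "")
                    + out + "->" + fsubs)
            blk = coef * _einsum(spec, *arrays)
            ix = [store.o if letter_class(c) == "o" else store.v
                  for c in fsubs]
            grad[np.ix_(*ix)] += blk
    return grad


def f_gradient(terms, store: TensorStore, lam, n_occ, n_virt):
    """d(lam . residual)/d f as a full (n, n) matrix (blocks assembled by
    index class), at the amplitudes currently in the store."""
    n = n_occ + n_virt
    grad = np.zeros((n, n))
    for coef, out, factors in terms:
        for k, (name, subs) in enumerate(factors):
            if name != "f":
                continue
            others = [(n2, s2) for m, (n2, s2) in enumerate(factors) if m != k]
            arrays = [store.get(n2, s2) for n2, s2 in others] + [lam]
            spec = (",".join(s for _, s in others)
                    + ("," if others else "") + out + "->" + subs)
            blk = coef * _einsum(spec, *arrays)
            ix = [store.o if letter_class(c) == "o" else store.v for c in subs]
            grad[np.ix_(*ix)] += blk
    return grad
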