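"""Reed-Solomon coding over GF(256) with errors-and-erasures decoding.

Two codes protect every encoded strand library:

* an outer ``[n=255, k=185, d=71]`` code applied column-wise across the rows
  of a block, so that up to ``d - 1 = 70`` lost strands per block are pure
  erasures and fully recoverable;
* an inner ``[n=14, k=11, d=4]`` shortened code applied per strand over the
  2-byte row index plus 9 data bytes, correcting one byte error (or up to
  three erasures) within a strand.

Both are MDS codes (``d = n - k + 1``). The implementation is the classical
one: syndromes, Berlekamp-Massey with erasure initialization, Chien search,
and Forney's algorithm, over GF(2^8) with primitive polynomial 0x11d.
"""

from __future__ import annotations

__all__ = ["ReedSolomonError", "RSCode", "OUTER_CODE", "INNER_CODE"]

_PRIM = 0x11D

# log/antilog tables for GF(2^8); exp table doubled to avoid modular reduction.
GF_EXP = [0] * 512
GF_LOG = [0] * 256
_x = 1
for _i in range(255):
    GF_EXP[_i] = _x
    GF_LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM
for _i in range(255, 512):
    GF_EXP[_i] = GF_EXP[_i - 255]


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return GF_EXP[GF_LOG[a] + GF_LOG[b]]


def _gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("division by zero in GF(256)")
    if a == 0:
        return 0
    return GF_EXP[(GF_LOG[a] - GF_LOG[b]) % 255]


def _gf_pow(a: int, power: int) -> int:
    return GF_EXP[(GF_LOG[a] * power) % 255]


def _gf_inverse(a: int) -> int:
    return GF_EXP[255 - GF_LOG[a]]


def _poly_scale(p: list[int], x: int) -> list[int]:
    return [_gf_mul(c, x) for c in p]


def _poly_add(p: list[int], q: list[int]) -> list[int]:
    r = [0] * max(len(p), len(q))
    for i, c in enumerate(p):
        r[i + len(r) - len(p)] = c
    for i, c in enumerate(q):
        r[i + len(r) - len(q)] ^= c
    return r


def _poly_mul(p: list[int], q: list[int]) -> list[int]:
    r = [0] * (len(p) + len(q) - 1)
    for j, qc in enumerate(q):
        if qc == 0:
            continue
        for i, pc in enumerate(p):
            if pc:
                r[i + j] ^= _gf_mul(pc, qc)
    return r


def _poly_eval(p: list[int], x: int) -> int:
    y = p[0]
    for c in p[1:]:
        y = _gf_mul(y, x) ^ c
    return y


class ReedSolomonError(Exception):
    """Uncorrectable codeword (too many errors/erasures)."""


class RSCode:
    """A systematic Reed-Solomon code with ``nsym`` parity symbols.

    Codewords are ``message + parity``. ``nsym = n - k = d - 1``; the code
    corrects ``e`` errors and ``f`` erasures whenever ``2e + f <= nsym``.
    Shortened codes fall out naturally: a message shorter than ``255 - nsym``
    behaves as if left-padded with zeros.
    """

    def __init__(self, nsym: int):
        if not 1 <= nsym < 255:
            raise ValueError("nsym must be in [1, 254]")
        self.nsym = nsym
        g = [1]
        for i in range(nsym):
            g = _poly_mul(g, [1, _gf_pow(2, i)])
        self._gen = g

    @property
    def distance(self) -> int:
        return self.nsym + 1

    def encode(self, msg: bytes | list[int]) -> bytes:
        """Append ``nsym`` parity symbols to ``msg``."""
        msg = list(msg)
        if len(msg) + self.nsym > 255:
            raise ValueError(
                f"message of {len(msg)} symbols too long for nsym={self.nsym}"
            )
        gen = self._gen
        rem = msg + [0] * self.nsym
        for i in range(len(msg)):
            coef = rem[i]
            if coef:
                for j in range(1, len(gen)):
                    rem[i + j] ^= _gf_mul(gen[j], coef)
        return bytes(msg + rem[len(msg) :])

    def _syndromes(self, codeword: list[int]) -> list[int]:
        return [_poly_eval(codeword, _gf_pow(2, i)) for i in range(self.nsym)]

    def decode(
        self, codeword: bytes | list[int], erase_pos: list[int] | None = None
    ) -> bytes:
        """Correct ``codeword`` in place and return the message part.

        ``erase_pos`` are 0-based positions (within this codeword) known to be
        unreliable; their values are ignored. Raises
        :class:`ReedSolomonError` when correction capacity is exceeded.
        """
        cw = list(codeword)
        n = len(cw)
        erase_pos = sorted(set(erase_pos or []))
        if any(not 0 <= p < n for p in erase_pos):
            raise ValueError("erasure position outside codeword")
        if len(erase_pos) > self.nsym:
            raise ReedSolomonError(
                f"{len(erase_pos)} erasures exceed capacity {self.nsym}"
            )
        for p in erase_pos:
            cw[p] = 0
        synd = self._syndromes(cw)
        if max(synd) == 0:
            return bytes(cw[: n - self.nsym])
        # Positions are indexed from the right (coefficient exponents) for the
        # locator polynomials; shortened codes need no special handling.
        coef_pos = [n - 1 - p for p in erase_pos]
        err_loc = self._errata_locator_bm(synd, coef_pos)
        err_pos = self._find_errors(err_loc, n)
        cw = self._correct_errata(cw, synd, err_pos)
        if max(self._syndromes(cw)) != 0:
            raise ReedSolomonError("decoding failed (residual syndromes)")
        return bytes(cw[: n - self.nsym])

    def _errata_locator_bm(
        self, synd: list[int], erase_coef_pos: list[int]
    ) -> list[int]:
        """Berlekamp-Massey seeded with the erasure locator."""
        # Erasure locator: product of (alpha^p * x + 1) in descending powers.
        erase_loc = [1]
        for p in erase_coef_pos:
            erase_loc = _poly_mul([_gf_pow(2, p), 1], erase_loc)
        err_loc = list(erase_loc)
        old_loc = list(erase_loc)
        n_erase = len(erase_coef_pos)
        for i in range(self.nsym - n_erase):
            k = i + n_erase
            delta = synd[k]
            for j in range(1, len(err_loc)):
                delta ^= _gf_mul(err_loc[-(j + 1)], synd[k - j])
            old_loc.append(0)
            if delta != 0:
                if len(old_loc) > len(err_loc):
                    new_loc = _poly_scale(old_loc, delta)
                    old_loc = _poly_scale(err_loc, _gf_inverse(delta))
                    err_loc = new_loc
                err_loc = _poly_add(err_loc, _poly_scale(old_loc, delta))
        while err_loc and err_loc[0] == 0:
            err_loc.pop(0)
        errs = len(err_loc) - 1
        if (errs - n_erase) * 2 + n_erase > self.nsym:
            raise ReedSolomonError("too many errors to correct")
        return err_loc

    @staticmethod
    def _find_errors(err_loc: list[int], n: int) -> list[int]:
        """Chien-style search for the roots of the errata locator."""
        errs = len(err_loc) - 1
        pos = []
        # Evaluate the reciprocal locator so roots land at alpha^p with
        # p < n, covering shortened codewords directly.
        rev = err_loc[::-1]
        for i in range(n):
            if _poly_eval(rev, _gf_pow(2, i)) == 0:
                pos.append(n - 1 - i)
        if len(pos) != errs:
            raise ReedSolomonError("could not locate all errors")
        return pos

    def _correct_errata(
        self, cw: list[int], synd: list[int], err_pos: list[int]
    ) -> list[int]:
        """Forney's algorithm at the located positions."""
        n = len(cw)
        coef_pos = [n - 1 - p for p in err_pos]
        loc = [1]
        for p in coef_pos:
            loc = _poly_mul([_gf_pow(2, p), 1], loc)
        # Error evaluator: (syndromes * locator) mod x^nsym, descending powers.
        synd_rev = list(reversed(synd[: self.nsym]))
        omega = _poly_mul(synd_rev, loc)
        omega = omega[len(omega) - self.nsym :]
        for i, p in enumerate(coef_pos):
            xi = _gf_pow(2, p)
            xi_inv = _gf_inverse(xi)
            # Formal derivative of the locator evaluated at xi_inv.
            denom = 1
            for j, q in enumerate(coef_pos):
                if j != i:
                    denom = _gf_mul(denom, 1 ^ _gf_mul(xi_inv, _gf_pow(2, q)))
            if denom == 0:
                raise ReedSolomonError("Forney denominator is zero")
            # With Omega = S*Lambda mod x^nsym and Lambda'(xi_inv) =
            # xi * prod_{j!=i}(1 - Xj*xi_inv) in GF(2^m), the xi factors cancel.
            magnitude = _gf_div(_poly_eval(omega, xi_inv), denom)
            cw[err_pos[i]] ^= magnitude
        return cw


#: Outer code across strands of a block: [255, 185, 71].
OUTER_CODE = RSCode(nsym=70)
#: Inner per-strand code over index + data bytes: [14, 11, 4].
INNER_CODE = RSCode(nsym=3)
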