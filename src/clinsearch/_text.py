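"""Shared French text normalisation and the index analyzer.

Every component that compares text (de-identification, boilerplate
frequency table, trigger matching, segment headers, indexing, query
parsing) goes through the same folding rules so that offsets and token
identities agree across the pipeline.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "fold",
    "normalize_line",
    "analyze",
    "Token",
    "FRENCH_STOP_WORDS",
]

# Length-preserving substitutions for characters whose Unicode
# decomposition would change string length (offsets must survive folding).
_LIGATURES = {"œ": "o", "Œ": "O", "æ": "a", "Æ": "A", "’": "'", "‘": "'"}

FRENCH_STOP_WORDS = frozenset(
    """
    le la les l un une des de du d au aux a à et ou où est sont etait était
    ete été etre être il elle ils elles on nous vous je tu se sa son ses ce
    cette ces cet qui que quoi qu dont en dans par pour sur sous avec chez
    ne pas plus moins tres très bien y n m s t c j si comme mais donc or ni
    """.split()
)


@lru_cache(maxsize=4096)
def _fold_char(ch: str) -> str:
    if ch in _LIGATURES:
        return _LIGATURES[ch]
    decomposed = unicodedata.normalize("NFKD", ch)
    base = "".join(c for c in decomposed if not unicodedata.combining(c))
    # keep length stable: multi-char decompositions fall back to the original
    return base if len(base) == 1 else ch


def fold(text: str) -> str:
    """Lowercase and strip diacritics without changing string length."""
    return "".join(_fold_char(ch) for ch in text).lower()


_WS_RE = re.compile(r"\s+")


def normalize_line(line: str) -> str:
    """Canonical form of a document line for frequency counting."""
    return _WS_RE.sub(" ", fold(line)).strip()


@dataclass(frozen=True)
class Token:
    """One analyzed token with its character span in the source text."""

    text: str
    start: int
    end: int
    is_stop: bool


_WORD_RE = re.compile(r"[a-z0-9]+")
# elided clitics: l', d', qu', j', n', m', s', t', c'
_ELISION = frozenset({"l", "d", "qu", "j", "n", "m", "s", "t", "c"})


def _conflate(token: str) -> str:
    """Light gender/number conflation: strip a final -es/-s/-e.

    At each step only the longest matching suffix is attempted, and only
    when the remaining stem keeps at least 4 characters; stripping runs to
    a fixpoint so the map is idempotent (*fausses* → *faus*, like *faux*
    would not, but re-analyzing its own output is stable). Digits are
    left alone.
    """
    if any(ch.isdigit() for ch in token):
        return token
    while True:
        for suffix in ("es", "s", "e"):
            if token.endswith(suffix):
                stem = token[: -len(suffix)]
                if len(stem) >= 4:
                    token = stem
                    break
                return token
        else:
            return token


def analyze(text: str) -> list[Token]:
    """Tokenize French clinical text for indexing and querying.

    Lowercases, strips diacritics, splits on non-alphanumerics (which
    also resolves elisions such as *l'abcès*), marks stop words, and
    applies the conflation rule. Elided clitics are kept as stop tokens
    so that positions stay aligned with the surface text.
    """
    out: list[Token] = []
    folded = fold(text)
    for m in _WORD_RE.finditer(folded):
        raw = m.group()
        if raw in _ELISION and m.end() < len(folded) and folded[m.end()] == "'":
            out.append(Token(raw, m.start(), m.end(), True))
            continue
        tok = _conflate(raw)
        out.append(Token(tok, m.start(), m.end(), raw in FRENCH_STOP_WORDS))
    return out
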