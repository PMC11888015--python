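"""Syllable counting: packaged dictionary first, heuristic fallback.

The heuristic counts vowel groups (a, e, i, o, u, y) and then applies the
classic orthographic corrections: a final silent ``e`` is dropped, a
syllabic ``-le``/``-les`` after a consonant is kept, and silent ``-es`` /
``-ed`` endings are dropped unless the preceding consonant forces an extra
syllable (``buses``, ``wanted``).
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

from .errors import ValidationError

_VOWEL_GROUP = re.compile(r"[aeiouy]+")
_LETTERS = re.compile(r"[a-z]+")


@lru_cache(maxsize=1)
def syllable_dictionary() -> dict[str, int]:
    """The packaged hand-counted word -> syllables table."""
    table: dict[str, int] = {}
    text = resources.files("webqual.data").joinpath("syllables.txt").read_text("utf-8")
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        word, count = line.rsplit(None, 1)
        table[word.lower()] = int(count)
    return table


def _heuristic(chunk: str) -> int:
    groups = _VOWEL_GROUP.findall(chunk)
    count = len(groups)
    if count <= 1:
        return max(count, 1)
    if chunk.endswith("le") and len(chunk) > 2 and chunk[-3] not in "aeiouy":
        pass  # syllabic -le: keep the group
    elif chunk.endswith("les") and len(chunk) > 3 and chunk[-4] not in "aeiouy":
        pass
    elif chunk.endswith("e"):
        count -= 1  # silent final e
    elif chunk.endswith("es") and len(chunk) > 2 and chunk[-3] not in "aeiouysxz":
        count -= 1  # silent -es (makes, times) but not buses/boxes
    elif chunk.endswith("ed") and len(chunk) > 2 and chunk[-3] not in "aeiouytd":
        count -= 1  # silent -ed (helped) but not wanted/needed
    return max(count, 1)


def count_syllables(word: str) -> int:
    """Syllables in one word (>= 1).

    Hyphenated words are counted part by part. Raises
    :class:`~webqual.errors.ValidationError` when the word has no letters.
    """
    chunks = _LETTERS.findall(word.lower())
    if not chunks:
        raise ValidationError(f"cannot syllabify {word!r}: no letters")
    table = syllable_dictionary()
    total = 0
    for chunk in chunks:
        total += table.get(chunk) or _heuristic(chunk)
    return total
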