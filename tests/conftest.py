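import numpy as np
import pytest

from webqual.model import Corpus, RatingSet, WebsiteRecord


def make_rating(website_id="w1", rater_id="r1", discern_total=42,
                jama=(True, False, False, False), content=(2, 2, 1, 2, 0, 1)):
    """A valid RatingSet whose DISCERN items sum to ``discern_total``."""
    assert 16 <= discern_total <= 80
    items = [1] * 16
    remaining = discern_total - 16
    i = 0
    while remaining > 0:
        if items[i] < 5:
            items[i] += 1
            remaining -= 1
        i = (i + 1) % 16
    return RatingSet(website_id=website_id, rater_id=rater_id,
                     discern=tuple(items), jama=jama, content=content)


def make_record(wid="w1", category="academic", text="Delirium is common. It is serious.",
                **kw):
    defaults = dict(id=wid, url=f"https://example.org/{wid}", category=category, text=text)
    defaults.update(kw)
    return WebsiteRecord(**defaults)


@pytest.fixture
def tiny_corpus():
    """3 records x 2 raters, no adjudication needed."""
    records = [
        make_record("w1", "academic"),
        make_record("w2", "commercial"),
        make_record("w3", "government"),
    ]
    ratings = []
    for wid, total in (("w1", 40), ("w2", 50), ("w3", 60)):
        ratings.append(make_rating(wid, "ra", total))
        ratings.append(make_rating(wid, "rb", total + 2))
    return Corpus(records=records, ratings=ratings)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
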