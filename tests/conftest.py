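import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_frame(rows):
    """Build a canonical tweets frame from compact tuples.

    Each row: (user_id, iso_utc_timestamp, utc_offset_seconds, text,
    is_retweet[, period]).
    """
    has_period = rows and len(rows[0]) == 6
    cols = ["user_id", "created_at_utc", "utc_offset_seconds", "text", "is_retweet"]
    if has_period:
        cols.append("period")
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "tweet_id", [f"t{i}" for i in range(len(df))])
    df["created_at_utc"] = pd.to_datetime(df["created_at_utc"], utc=True).dt.tz_localize(None)
    df["utc_offset_seconds"] = df["utc_offset_seconds"].astype(np.int64)
    df["is_retweet"] = df["is_retweet"].astype(bool)
    return df


@pytest.fixture(scope="session")
def drug_lexicon():
    from ssritweets.lexicon import default_lexicon

    return default_lexicon()


@pytest.fixture(scope="session")
def tagger_entries():
    from ssritweets.text import default_tagger

    return default_tagger().entries


@pytest.fixture(scope="session")
def lexicons():
    from ssritweets.text import default_lexicons

    return default_lexicons()


@pytest.fixture(scope="session")
def small_cohort():
    """One 25-user synthetic cohort shared by read-only tests."""
    from ssritweets.simulate import CohortConfig, generate_cohort

    cfg = CohortConfig.compact(n_users=25)
    return generate_cohort(cfg, seed=11)
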