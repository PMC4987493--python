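import numpy as np
import pytest

from cqarank.concept_recognition import bundled_lexicon
from cqarank.corpus_io import Answer, QAThread
from cqarank.features import load_stoplist

# the worked example triple used throughout the suite
WORKED_Q_P = "Anxiety medication for drug/alcohol addiction?"
WORKED_Q_T = (
    "Is chlordiazepoxide/librium a good medication for alcohol withdrawal "
    "and the associated anxiety?"
)
WORKED_A_T = (
    "Chlordiazepoxide has been the standard drug used for rapid alcohol detox "
    "for decades and has stood the test of time. The key word is rapid the drug "
    "should really only be given for around a week. Starting at 100 mg on day 1 "
    "and reducing the dose every day to reach zero on day 8. In my experience, "
    "it deals well with both the physical and mental symptoms of withdrawal. "
    "Looking ahead, he will still need an alternative management for his anxiety "
    "to replace the alcohol. Therapy may help, possibly in a group setting"
)


@pytest.fixture(scope="session")
def lexicon():
    return bundled_lexicon()


@pytest.fixture(scope="session")
def stops():
    return load_stoplist()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_thread(thread_id, title, answers=None, description=""):
    answers = answers or [("an answer.", True, 0)]
    return QAThread(
        thread_id=thread_id,
        title=title,
        description=description,
        answers=[Answer(text=t, is_best=b, likes=l) for t, b, l in answers],
    )


@pytest.fixture
def yes_no_corpus():
    """Three yes-no threads with two answers each."""
    return [
        make_thread(
            "t1",
            "Can a recovered alcoholic drink again?",
            [("No, relapse risk stays high.", True, 2), ("Some manage moderation.", False, 9)],
        ),
        make_thread(
            "t2",
            "Is chlordiazepoxide a good medication for alcohol withdrawal?",
            [("Yes, it is the standard detox drug.", True, 5), ("Ask a doctor first.", False, 1)],
        ),
        make_thread(
            "t3",
            "Should I stop drinking cold turkey?",
            [("Never without medical help.", True, 3), ("Taper slowly instead.", False, 2)],
        ),
    ]
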