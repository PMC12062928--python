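import pytest

from playface.ethogram import (ExpressionEvent, PatternEvent, PlaySession,
                               packaged_ethogram, packaged_group_table)


@pytest.fixture(scope="session")
def ethogram():
    return packaged_ethogram()


@pytest.fixture(scope="session")
def group_table():
    return packaged_group_table()


def make_pattern(time, actor="A", target="B", pattern="play bite",
                 category="offensive"):
    return PatternEvent(time=time, actor=actor, target=target,
                        pattern=pattern, category=category)


def make_expression(onset, emitter="A", expr_type="PF",
                    perception="frontal", duration=1.0):
    return ExpressionEvent(onset=onset, offset=onset + duration,
                           emitter=emitter, expr_type=expr_type,
                           partner_perception=perception)


def make_session(patterns=(), expressions=(), session_id="s1", end=None,
                 player_a="A", player_b="B", group_id="G"):
    times = ([p.time for p in patterns] + [e.offset for e in expressions]) or [1.0]
    end = end if end is not None else max(times)
    return PlaySession(session_id=session_id, group_id=group_id,
                       player_a=player_a, player_b=player_b,
                       start=0.0, end=end,
                       pattern_events=list(patterns),
                       expression_events=list(expressions))


@pytest.fixture
def session_factory():
    return make_session
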