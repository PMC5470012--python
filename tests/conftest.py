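import numpy as np
import pytest

from par24.catalog import ActivityDefinition, Catalog, demo_catalog
from par24.diary import ActivityEntry, DiaryDay


@pytest.fixture(scope="session")
def catalog():
    return demo_catalog()


@pytest.fixture(scope="session")
def tiny_catalog():
    """Minimal hand-built catalog with one activity per scoring mode."""
    return Catalog.from_definitions(
        [
            ActivityDefinition("SIT", "sitting quietly", 1, {"none": 1.0}),
            ActivityDefinition("WALK", "walking", 4, {"light": 2.8, "medium": 3.5, "hard": 4.3}),
            ActivityDefinition(
                "DESK", "desk work", 6, {}, met_sitting=1.3, met_standing=1.8
            ),
            ActivityDefinition("CHORES", "light chores", 5, {"none": 2.0}),
            ActivityDefinition("RUN", "running", 9, {"light": 6.0, "medium": 8.3, "hard": 11.0}),
        ]
    )


def make_day(segments, participant_id="P001", recall_index=1):
    """Diary from (code, start, end[, effort[, standing]]) tuples."""
    entries = []
    for segment in segments:
        code, start, end = segment[:3]
        effort = segment[3] if len(segment) > 3 else None
        standing = segment[4] if len(segment) > 4 else None
        entries.append(
            ActivityEntry(
                code=code, start_min=start, end_min=end,
                effort=effort, standing_fraction=standing,
            )
        )
    return DiaryDay(participant_id=participant_id, entries=tuple(entries),
                    recall_index=recall_index)


@pytest.fixture
def full_day_factory():
    return make_day
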