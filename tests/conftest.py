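import pytest

from markresight import Dataset, MarkingRecord, SurveyRecord


@pytest.fixture
def toy_dataset() -> Dataset:
    """Two periods, two methods, two surveys per (period, method)."""
    surveys = [
        SurveyRecord("Dec 2016", 1, "AM", "SO", 100, 900),
        SurveyRecord("Dec 2016", 1, "PM", "SO", 120, 680),
        SurveyRecord("Dec 2016", 1, "AM", "UAV", 95, 1365),
        SurveyRecord("Dec 2016", 1, "PM", "UAV", 90, 1210),
        SurveyRecord("Dec 2017", 1, "AM", "SO", 150, 1450),
        SurveyRecord("Dec 2017", 2, "AM", "SO", 140, 1260),
        SurveyRecord("Dec 2017", 1, "AM", "UAV", 110, 1890),
        SurveyRecord("Dec 2017", 2, "AM", "UAV", 105, 1995),
    ]
    markings = [MarkingRecord("Dec 2016", 2000), MarkingRecord("Dec 2017", 2000)]
    return Dataset(surveys, markings)
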