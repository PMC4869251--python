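import pytest

from crisparray import GenomeRecord, load_repeat_bank, run_pipeline
from crisparray.model import forward_unit_intervals
from crisparray.report import ReportOptions


@pytest.fixture(scope="session")
def bank():
    return load_repeat_bank()


@pytest.fixture(scope="session")
def report_all():
    """Report options that keep questionable arrays visible to assertions."""
    return ReportOptions(min_score_to_report=0.0)


def forward_units(array, genome: GenomeRecord):
    return forward_unit_intervals(array, len(genome.sequence))


def detect(genome, **kwargs):
    kwargs.setdefault("options", ReportOptions(min_score_to_report=0.0))
    return run_pipeline(genome, **kwargs)
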