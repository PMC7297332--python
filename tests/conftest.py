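import pytest

from cathlar import (
    GeneratorConfig,
    OperatorDose,
    ProcedureRecord,
    ProcedureType,
    Role,
    Sex,
    generate,
    load_default_params,
    load_default_tables,
)


@pytest.fixture(scope="session")
def params():
    return load_default_params()


@pytest.fixture(scope="session")
def tables():
    return load_default_tables()


@pytest.fixture(scope="session")
def small_log():
    """A 20-procedure synthetic log with both roles present."""
    return generate(GeneratorConfig(n_procedures=20, seed=7))


def make_record(
    pid="P1",
    ptype=ProcedureType.CA_PCI,
    dap=100.0,
    doses=((Role.PRIMARY, 50.0),),
    **kwargs,
):
    """Minimal valid procedure record for targeted tests."""
    operators = [
        OperatorDose(
            operator_id=f"OP{i}",
            role=role,
            age=45.0,
            sex=Sex.M,
            epd_dose_usv=dose,
        )
        for i, (role, dose) in enumerate(doses)
    ]
    defaults = dict(
        procedure_id=pid,
        procedure_type=ptype,
        fluoro_time_min=10.0,
        fluoro_kv=95.0,
        fluoro_ma=12.0,
        acq_kv=85.0,
        acq_ma=780.0,
        acq_time_s=50.0,
        dap_gycm2=dap,
        operator_doses=operators,
    )
    defaults.update(kwargs)
    return ProcedureRecord(**defaults)
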