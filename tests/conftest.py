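import pytest

from otplan.cli import compile_inputs
from otplan.fixtures import FixtureSpec, generate_fixture

LABWARE_CSV = """\
Name,Labware,Slot,Working Volume,Source,Mixing,Final
tubes,opentrons_24_tuberack_nest_1.5ml_snapcap,1,1400,Y,N,N
mix,corning_96_wellplate_360ul_flat,2,200,N,Y,N
plate1,corning_96_wellplate_360ul_flat,3,200,N,N,Y
tips20,opentrons_96_tiprack_20ul,4,0,N,N,N
tips300,opentrons_96_tiprack_300ul,5,0,N,N,N
trash,agilent_1_reservoir_290ml,11,0,N,N,N
"""

STOCK_CSV = """\
Component,Sample,Well Location,Volume,Concentration,Target Volume,Speed,Transfer Volume,Dilutant,Diluent
DNA,0,tubes:A1,1000,100 ng/ul,100,,,N,N
Mg,0,tubes:A2,1000,50 mM,100,,,N,N
water,0,tubes:A3,1300,0,100,,,Y,N
"""

PARAMS_CSV = """\
DNA,Mg
10,5
20,0
"""

PIPETTES_CSV = """\
Pipette,P20,P300
Mount,left,right
Aspirate Rate,7.5,150
Dispense Rate,7.5,300
Tip Rack,tips20,tips300
Trash Container,trash,trash
"""


@pytest.fixture
def hand_texts():
    return {
        "labware_inventory": LABWARE_CSV,
        "stock_inventory": STOCK_CSV,
        "experimental_parameters": PARAMS_CSV,
        "pipette_settings": PIPETTES_CSV,
    }


@pytest.fixture(scope="session")
def feasible_fixture():
    return generate_fixture(FixtureSpec(seed=7, n_samples=4, n_reagents=3))


@pytest.fixture(scope="session")
def compiled(feasible_fixture):
    return compile_inputs(feasible_fixture.as_dict())
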