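import numpy as np
import pytest

from ctweigh import (
    PhantomComponent,
    PhantomSpec,
    TableSpec,
    body_with_table,
    generate_phantom,
)


@pytest.fixture
def simple_body_spec():
    """A table-free torso-like phantom (fat shell, muscle core, bone rod)."""
    spec = body_with_table(rows=96, cols=96, slices=4)
    spec.table = None
    return spec


@pytest.fixture
def tabled_body_spec():
    """The same body resting above a flat 8-voxel table band."""
    return body_with_table(rows=96, cols=96, slices=4)


@pytest.fixture
def simple_body(simple_body_spec):
    return generate_phantom(simple_body_spec)


@pytest.fixture
def tabled_body(tabled_body_spec):
    return generate_phantom(tabled_body_spec)


@pytest.fixture
def muscle_box_spec():
    """A single 10x10x10-voxel muscle box at 1 mm isotropic spacing."""
    comp = PhantomComponent(
        shape="box", center=(4.5, 20.5, 20.5), axes=(4.5, 4.5, 4.5), hu=50.0, tissue_class="muscle"
    )
    return PhantomSpec(image_rows=48, image_cols=48, slice_count=12, components=[comp])


def curved_table_spec(a, c0, band_height, rows=160, cols=128, hu=250.0, slices=4, **kwargs):
    """Body above a parabolic table with vertex near the image center."""
    table = TableSpec(a=a, b=-a * cols, c=c0, band_height=band_height, hu=hu)
    return body_with_table(rows=rows, cols=cols, slices=slices, table=table, **kwargs)
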