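import textwrap

import pandas as pd
import pytest

from litnet import Document, GeneDiseaseAssociations, TermDictionary

MEDLINE_XML = textwrap.dedent("""\
    <?xml version="1.0" encoding="UTF-8"?>
    <PubmedArticleSet>
      <PubmedArticle>
        <MedlineCitation>
          <PMID>101</PMID>
          <Article>
            <ArticleTitle>Leptin receptor signalling in obesity</ArticleTitle>
            <Abstract>
              <AbstractText>LEPR expression rises with adiposity.</AbstractText>
            </Abstract>
            <Journal><JournalIssue><PubDate><Year>2019</Year></PubDate></JournalIssue></Journal>
          </Article>
          <MeshHeadingList>
            <MeshHeading>
              <DescriptorName UI="D009765">Obesity</DescriptorName>
              <QualifierName UI="Q000235">genetics</QualifierName>
            </MeshHeading>
            <MeshHeading>
              <DescriptorName UI="D006801">Humans</DescriptorName>
            </MeshHeading>
          </MeshHeadingList>
        </MedlineCitation>
      </PubmedArticle>
      <PubmedArticle>
        <MedlineCitation>
          <PMID>102</PMID>
          <Article>
            <ArticleTitle>A record without an abstract</ArticleTitle>
          </Article>
        </MedlineCitation>
      </PubmedArticle>
    </PubmedArticleSet>
    """)


@pytest.fixture
def medline_xml(tmp_path):
    path = tmp_path / "corpus.xml"
    path.write_text(MEDLINE_XML, encoding="utf-8")
    return path


@pytest.fixture
def tiny_docs():
    return [
        Document(pmid="1", title="LEPR study", abstract="LEPR expression in adipose tissue",
                 mesh_terms=("Obesity", "Humans"), year=2018),
        Document(pmid="2", title="Leptin biology", abstract="leptin receptor and leptin signalling",
                 mesh_terms=("Obesity",), year=2019),
        Document(pmid="3", title="Unrelated", abstract="nothing to see here",
                 mesh_terms=("Humans",), year=2020),
        Document(pmid="4", title="No abstract", abstract="", mesh_terms=(), year=None),
    ]


@pytest.fixture
def gene_dict():
    return TermDictionary(
        namespace="gene",
        entries={
            "LEP": ("LEP", ("leptin",)),
            "LEPR": ("LEPR", ("leptin receptor",)),
            "FTO": ("FTO", ()),
        },
    )


@pytest.fixture
def gda_fixture():
    rows = [
        ("FTO", "C0028754", "Obesity", "11"),
        ("FTO", "C0028754", "Obesity", "12"),
        ("FTO", "C0011849", "Diabetes", "13"),
        ("LEP", "C0028754", "Obesity", "11"),
        ("LEP", "C0028754", "Obesity", "11"),  # exact duplicate
    ]
    return GeneDiseaseAssociations(
        pd.DataFrame(rows, columns=["gene", "disease_id", "disease_name", "pmid"])
    )
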