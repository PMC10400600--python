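# Default moonprobe configuration.
#
# categories: functional-category name -> case-insensitive keywords matched
#   as substrings of each gene's product annotation or gene symbol. The
#   category names mirror those used in the enrichment tables; keyword lists
#   are a best-effort reconstruction over RefSeq product strings.
# gene_sets: curated gene sets; the "moonlighting" set lists gene symbols and
#   product keywords for the curated moonlighting proteins. Each annotated
#   isoform matching any term counts separately.

categories:
  Cell wall biogenesis: ["cell wall"]
  Secretion: ["secretion", "secreted"]
  Inner membrane: ["inner membrane"]
  Outer membrane: ["outer membrane"]
  Plasma membrane: ["plasma membrane"]
  Membrane: ["membrane"]
  Transmembrane: ["transmembrane"]
  Fatty acid: ["fatty acid", "fatty-acid"]
  Peptidoglycan: ["peptidoglycan"]
  Lipoprotein: ["lipoprotein"]
  Hypothetical protein: ["hypothetical protein"]
  tRNA ligase: ["trna ligase", "--trna ligase", "trna synthetase"]
  Ribosomal protein: ["ribosomal protein"]
  PE-PGRS: ["pe-pgrs"]
  PPE family: ["ppe family"]
  Esx: ["esx"]
  Efflux: ["efflux"]
  Transporter: ["transporter"]
  Exporter: ["exporter"]
  Permease: ["permease"]
  Mycolate synthesis: ["mycol"]
  Release factor: ["release factor"]
  Anti-Sigma factors: ["anti-sigma"]
  Cell division: ["cell division"]

gene_sets:
  moonlighting-like:
    - "moonlighting-like"
  moonlighting:
    - "methyltransferase erm"
    - "rRNA adenine N-6-methyltransferase"
    - "glutamate racemase"
    - "murI"
    - "elongation factor Tu"
    - "tuf"
    - "malate synthase"
    - "aceB"
    - "glcB"
    - "cysteine desulfurase"
    - "csd"
    - "iscS"
    - "gamma-glutamyl phosphate reductase"
    - "glutamate-5-semialdehyde dehydrogenase"
    - "proA"
    - "glucose-6-phosphate isomerase"
    - "pgi"
    - "6-phosphofructokinase"
    - "pfkA"
    - "pfkB"
    - "6-phosphogluconate dehydrogenase"
    - "gnd"
    - "enolase"
    - "eno"
    - "triose-phosphate isomerase"
    - "triosephosphate isomerase"
    - "tpiA"
    - "elongation factor G"
    - "fusA"
    - "endopeptidase O"
    - "pepO"
    - "DNA-directed RNA polymerase subunit beta"
    - "rpoB"
    - "chaperone protein DnaK"
    - "molecular chaperone DnaK"
    - "dnaK"
    - "chaperonin GroEL"
    - "groEL"
    - "groL"
    - "mycolyltransferase"
    - "antigen 85"
    - "fbpA"
    - "fbpB"
    - "fbpC"
    - "superoxide dismutase"
    - "sodA"
    - "sodC"
    - "glyceraldehyde-3-phosphate dehydrogenase"
    - "gapA"
    - "phosphoglycerate kinase"
    - "pgk"
    - "fructose-bisphosphate aldolase"
    - "fba"
    - "phosphoglycerate mutase"
    - "gpmA"
    - "gpmB"
    - "gpmM"
    - "glutamine synthetase"
    - "glnA"
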