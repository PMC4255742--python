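# ISA base vocabulary mapping: a one-to-one rendering of the ISA-Tab 1.0
# syntactic vocabulary into the project ISA vocabulary namespace
# (http://purl.org/isaterms/). This enumeration of the vocabulary beyond the
# elements with established external semantics is this package's own.
# Rows are: ISA element, class label, class IRI.
# Rows whose element is a property name (e.g. "has input") define the
# property vocabulary the converter wires individuals with; any later
# mapping file may override them.
Investigation,investigation,http://purl.org/isaterms/Investigation
Study,study,http://purl.org/isaterms/Study
Study Design,study design,http://purl.org/isaterms/StudyDesign
Study Factor,study factor,http://purl.org/isaterms/StudyFactor
Study Assay,study assay,http://purl.org/isaterms/StudyAssay
Study Protocol,study protocol,http://purl.org/isaterms/StudyProtocol
Study Group,study group,http://purl.org/isaterms/StudyGroup
Factor Value,factor value,http://purl.org/isaterms/FactorValue
Source Name,source,http://purl.org/isaterms/Source
Sample Name,sample,http://purl.org/isaterms/Sample
Extract Name,extract,http://purl.org/isaterms/Extract
Labeled Extract Name,labeled extract,http://purl.org/isaterms/LabeledExtract
Material,material,http://purl.org/isaterms/Material
Raw Data File,raw data file,http://purl.org/isaterms/RawDataFile
Derived Data File,derived data file,http://purl.org/isaterms/DerivedDataFile
Data File,data file,http://purl.org/isaterms/DataFile
Protocol REF,process,http://purl.org/isaterms/Process
Characteristics,characteristic,http://purl.org/isaterms/Characteristic
Parameter Value,parameter value,http://purl.org/isaterms/ParameterValue
Unit,unit,http://purl.org/isaterms/Unit
Comment,comment,http://purl.org/isaterms/Comment
balanced design,balanced design,http://purl.org/isaterms/BalancedDesign
has part,has part,http://purl.org/isaterms/hasPart
has design,has design,http://purl.org/isaterms/hasDesign
has factor,has factor,http://purl.org/isaterms/hasFactor
has level,has level,http://purl.org/isaterms/hasLevel
has group,has group,http://purl.org/isaterms/hasGroup
has member,has member,http://purl.org/isaterms/hasMember
has size,has size,http://purl.org/isaterms/hasSize
has assay,has assay,http://purl.org/isaterms/hasAssay
has protocol,has protocol,http://purl.org/isaterms/hasProtocol
has input,has input,http://purl.org/isaterms/hasInput
has output,has output,http://purl.org/isaterms/hasOutput
executes protocol,executes protocol,http://purl.org/isaterms/executesProtocol
has characteristic,has characteristic,http://purl.org/isaterms/hasCharacteristic
has parameter value,has parameter value,http://purl.org/isaterms/hasParameterValue
has unit,has unit,http://purl.org/isaterms/hasUnit
identifier,identifier,http://purl.org/isaterms/identifier
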