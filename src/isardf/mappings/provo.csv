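# PROV-O framework mapping: materials and data files are provenance
# entities, protocol applications are activities; process wiring uses the
# PROV-O used/generated properties (activity -> entity direction matches the
# converter's has-input/has-output direction).
Source Name,entity,http://www.w3.org/ns/prov#Entity
Sample Name,entity,http://www.w3.org/ns/prov#Entity
Extract Name,entity,http://www.w3.org/ns/prov#Entity
Labeled Extract Name,entity,http://www.w3.org/ns/prov#Entity
Material,entity,http://www.w3.org/ns/prov#Entity
Raw Data File,entity,http://www.w3.org/ns/prov#Entity
Derived Data File,entity,http://www.w3.org/ns/prov#Entity
Data File,entity,http://www.w3.org/ns/prov#Entity
Protocol REF,activity,http://www.w3.org/ns/prov#Activity
Study Protocol,plan,http://www.w3.org/ns/prov#Plan
has input,used,http://www.w3.org/ns/prov#used
has output,generated,http://www.w3.org/ns/prov#generated
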