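<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema of the annotation XML container, format version 1.0. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">

  <xs:simpleType name="boolStr">
    <xs:restriction base="xs:string">
      <xs:enumeration value="true"/>
      <xs:enumeration value="false"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="ssClass">
    <xs:restriction base="xs:string">
      <xs:enumeration value="H"/>
      <xs:enumeration value="G"/>
      <xs:enumeration value="E"/>
      <xs:enumeration value="C"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="roleType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="structure"/>
      <xs:enumeration value="model"/>
      <xs:enumeration value="sequence"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="unitInterval">
    <xs:restriction base="xs:double">
      <xs:minInclusive value="0"/>
      <xs:maxInclusive value="1"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="entropySymbol">
    <xs:restriction base="xs:string">
      <xs:pattern value="[*0-9]"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="consensusSymbol">
    <xs:restriction base="xs:string">
      <xs:pattern value="[ab3]"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="disorderScale">
    <xs:restriction base="xs:integer">
      <xs:minInclusive value="0"/>
      <xs:maxInclusive value="9"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="alignment-annotation">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="provenance">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="parameter" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="name" type="xs:string" use="required"/>
                  <xs:attribute name="value" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="tool" type="xs:string" use="required"/>
            <xs:attribute name="release" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="alignment">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="sequence" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="gapped" type="xs:string"/>
                    <xs:element name="residues" minOccurs="0">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="residue" maxOccurs="unbounded">
                            <xs:complexType>
                              <xs:attribute name="index" type="xs:positiveInteger" use="required"/>
                              <xs:attribute name="ss" type="ssClass" use="required"/>
                              <xs:attribute name="buried" type="boolStr" use="required"/>
                              <xs:attribute name="hb-amide" type="boolStr" use="required"/>
                              <xs:attribute name="hb-carbonyl" type="boolStr" use="required"/>
                              <xs:attribute name="rel-sasa" type="xs:double"/>
                              <xs:attribute name="positive-phi" type="boolStr"/>
                              <xs:attribute name="depth" type="xs:double"/>
                              <xs:attribute name="chain-contact" type="xs:string"/>
                              <xs:attribute name="ligand-contact" type="xs:string"/>
                              <xs:attribute name="contacts" type="xs:string"/>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="prediction" minOccurs="0">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="residue" maxOccurs="unbounded">
                            <xs:complexType>
                              <xs:attribute name="index" type="xs:positiveInteger" use="required"/>
                              <xs:attribute name="helix" type="unitInterval" use="required"/>
                              <xs:attribute name="strand" type="unitInterval" use="required"/>
                              <xs:attribute name="coil" type="unitInterval" use="required"/>
                              <xs:attribute name="disorder" type="disorderScale" use="required"/>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                  <xs:attribute name="role" type="roleType" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="columns" type="xs:positiveInteger" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="columns">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="column" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="index" type="xs:positiveInteger" use="required"/>
                  <xs:attribute name="entropy" type="unitInterval" use="required"/>
                  <xs:attribute name="entropy-symbol" type="entropySymbol" use="required"/>
                  <xs:attribute name="consensus-ss" type="consensusSymbol"/>
                  <xs:attribute name="rmsd" type="xs:double"/>
                  <xs:attribute name="rmsd-bin" type="xs:nonNegativeInteger"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="superposition" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="transform" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                  <xs:attribute name="rotation" type="xs:string" use="required"/>
                  <xs:attribute name="translation" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="weight" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="column" type="xs:positiveInteger" use="required"/>
                  <xs:attribute name="value" type="xs:double" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="iterations" type="xs:nonNegativeInteger" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="pid-table" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="pid" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                  <xs:attribute name="value" type="xs:double" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
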