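<?xml version="1.0" encoding="UTF-8"?>
<!-- Plugin descriptor schema (version 1). A repo-defined stand-in for the
     analysis-grid plugin configuration format: identity and type of the
     plugin, its input/output slots, environment entries injected into
     plugin scripts, and the SDK command-line templates used to lower
     fetch/push commands. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">
  <xs:simpleType name="pluginType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="aligner"/>
      <xs:enumeration value="alignment-analysis"/>
      <xs:enumeration value="resource"/>
      <xs:enumeration value="artifact-install"/>
      <xs:enumeration value="task"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="slot">
    <xs:attribute name="name" type="xs:string" use="required"/>
    <xs:attribute name="fileType" type="xs:string"/>
  </xs:complexType>

  <xs:element name="plugin">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="errorManagement" minOccurs="0">
          <xs:complexType>
            <xs:attribute name="policy" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="slots" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="input" type="slot" minOccurs="0" maxOccurs="unbounded"/>
              <xs:element name="output" type="slot" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="env" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="entry" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="name" type="xs:string" use="required"/>
                  <xs:attribute name="value" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="sdk" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="fetch" type="xs:string" minOccurs="0"/>
              <xs:element name="push" type="xs:string" minOccurs="0"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="type" type="pluginType" use="required"/>
      <xs:attribute name="version" type="xs:integer"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
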