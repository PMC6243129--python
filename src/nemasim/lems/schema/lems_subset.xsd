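<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema for the implemented LEMS subset: flat ComponentTypes with
     parameters, requirements, exposures, event ports and dynamics
     (state variables, derived variables, time derivatives, on-start,
     edge-triggered conditions, event handlers), Component instances with
     quantity-string parameter bindings, and NeuronModel wiring. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:complexType name="stateAssignment">
    <xs:attribute name="variable" type="xs:string" use="required"/>
    <xs:attribute name="value" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="dynamics">
    <xs:choice minOccurs="0" maxOccurs="unbounded">
      <xs:element name="StateVariable">
        <xs:complexType>
          <xs:attribute name="name" type="xs:string" use="required"/>
          <xs:attribute name="dimension" type="xs:string" use="required"/>
        </xs:complexType>
      </xs:element>
      <xs:element name="DerivedVariable">
        <xs:complexType>
          <xs:attribute name="name" type="xs:string" use="required"/>
          <xs:attribute name="value" type="xs:string" use="required"/>
        </xs:complexType>
      </xs:element>
      <xs:element name="TimeDerivative">
        <xs:complexType>
          <xs:attribute name="variable" type="xs:string" use="required"/>
          <xs:attribute name="value" type="xs:string" use="required"/>
        </xs:complexType>
      </xs:element>
      <xs:element name="OnStart">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="StateAssignment" type="stateAssignment" minOccurs="0" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="OnCondition">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="StateAssignment" type="stateAssignment" minOccurs="0" maxOccurs="unbounded"/>
            <xs:element name="EventOut" minOccurs="0">
              <xs:complexType>
                <xs:attribute name="port" type="xs:string" use="required"/>
              </xs:complexType>
            </xs:element>
          </xs:sequence>
          <xs:attribute name="test" type="xs:string" use="required"/>
        </xs:complexType>
      </xs:element>
      <xs:element name="OnEvent">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="StateAssignment" type="stateAssignment" minOccurs="0" maxOccurs="unbounded"/>
          </xs:sequence>
          <xs:attribute name="port" type="xs:string" use="required"/>
        </xs:complexType>
      </xs:element>
    </xs:choice>
  </xs:complexType>

  <xs:complexType name="componentType">
    <xs:choice minOccurs="0" maxOccurs="unbounded">
      <xs:element name="Parameter">
        <xs:complexType>
          <xs:attribute name="name" type="xs:string" use="required"/>
          <xs:attribute name="dimension" type="xs:string" use="required"/>
        </xs:complexType>
      </xs:element>
      <xs:element name="Requirement">
        <xs:complexType>
          <xs:attribute name="name" type="xs:string" use="required"/>
          <xs:attribute name="dimension" type="xs:string" use="required"/>
        </xs:complexType>
      </xs:element>
      <xs:element name="Exposure">
        <xs:complexType>
          <xs:attribute name="name" type="xs:string" use="required"/>
          <xs:attribute name="variable" type="xs:string" use="required"/>
        </xs:complexType>
      </xs:element>
      <xs:element name="EventPort">
        <xs:complexType>
          <xs:attribute name="name" type="xs:string" use="required"/>
          <xs:attribute name="direction">
            <xs:simpleType>
              <xs:restriction base="xs:string">
                <xs:enumeration value="in"/>
                <xs:enumeration value="out"/>
              </xs:restriction>
            </xs:simpleType>
          </xs:attribute>
        </xs:complexType>
      </xs:element>
      <xs:element name="Dynamics" type="dynamics"/>
    </xs:choice>
    <xs:attribute name="name" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:element name="Lems">
    <xs:complexType>
      <xs:choice minOccurs="0" maxOccurs="unbounded">
        <xs:element name="ComponentType" type="componentType"/>
        <xs:element name="Component">
          <xs:complexType>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="type" type="xs:string" use="required"/>
            <xs:anyAttribute processContents="skip"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="NeuronModel">
          <xs:complexType>
            <xs:choice minOccurs="0" maxOccurs="unbounded">
              <xs:element name="Link">
                <xs:complexType>
                  <xs:attribute name="from" type="xs:string" use="required"/>
                  <xs:attribute name="exposure" type="xs:string" use="required"/>
                  <xs:attribute name="to" type="xs:string" use="required"/>
                  <xs:attribute name="requirement" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="EventLink">
                <xs:complexType>
                  <xs:attribute name="from" type="xs:string" use="required"/>
                  <xs:attribute name="port" type="xs:string" use="required"/>
                  <xs:attribute name="to" type="xs:string" use="required"/>
                  <xs:attribute name="targetPort" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:choice>
            <xs:attribute name="root" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:choice>
    </xs:complexType>
  </xs:element>

</xs:schema>
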